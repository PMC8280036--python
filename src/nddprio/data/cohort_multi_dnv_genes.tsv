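gene	dn_PTV	dn_Dmis	rvis	rvis_percentile	pli	pli_percentile
SCN2A	1	3	-2.51	1.05	1.00	0.72
MECP2	1	3	-0.32	30.25	0.70	24.62
MED13L	3	0	-1.61	3.34	1.00	0.57
GRIN2B	1	2	-2.48	1.10	1.00	2.19
KCNQ2	1	2	-1.25	5.97	1.00	5.39
CTNNB1	3	0	-1.07	8.10	1.00	4.20
TCF20	3	0	-3.82	0.34	1.00	2.84
ASH1L	2	0	-3.89	0.31	1.00	0.16
SATB2	2	0	-1.31	5.37	1.00	4.97
NRXN1	0	2	-1.88	2.30	1.00	3.22
BCL11A	2	0	-1.67	3.07	0.83	20.63
ADNP	2	0	-1.54	3.72	1.00	5.98
SHANK3	2	0	.	.	1.00	4.13
MSL2	2	0	-0.72	15.01	0.89	18.19
SYNE1	0	2	-1.10	7.70	3.75E-27	99.45
SYNGAP1	1	1	-2.30	1.36	1.00	1.79
BRAF	0	2	-0.97	9.63	1.00	2.83
GATAD2B	2	0	-0.65	16.92	1.00	6.34
LLGL1	0	2	-1.70	2.94	0.98	12.10
SLC2A1	0	2	-0.92	10.49	0.94	15.56
KDM5C	0	2	-2.71	0.88	1.00	7.02
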