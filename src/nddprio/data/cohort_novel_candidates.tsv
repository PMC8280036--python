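gene	qvalue
SMAD6	4.83E-04
SPG7	8.89E-04
MSL2	9.62E-04
CYP27C1	1.39E-03
ITSN1	1.89E-03
PSD3	2.11E-03
POLR3A	2.99E-03
UBR3	5.41E-03
GALNT18	7.34E-03
DCX	7.43E-03
LRRC4	2.56E-02
SPAG9	3.15E-02
ST3GAL6	3.23E-02
YTHDC1	8.48E-02
RRAGC	9.00E-02
DNAH17	9.58E-02
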