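# nddprio

Integrative candidate-gene prioritization for trio sequencing studies of
neurodevelopmental disorders (NDDs).

Targeted and exome trio studies identify de novo variants (DNVs) and rare
inherited variants in affected probands. Individually these variants rarely
reach significance; the evidence becomes compelling when it is pooled per
gene, weighed against the gene's background mutation rate, and cross-checked
against orthogonal functional data. `nddprio` implements that integration as
a reusable, tested pipeline:

1. **Variant classification and filtering** — trio genotypes give each
   variant an inheritance status (de novo, inherited paternal/maternal/
   unphased, or unknown when a parent is missing); protein-truncating
   variants (PTVs: stop-gain, stop-loss, frameshift, splicing) and
   deleterious missense variants (Dmis: ReVe score > 0.7) with minor allele
   frequency ≤ 0.1% in every population database are retained. X-linked
   hemizygous variants transmitted from heterozygous mothers to male
   probands are flagged separately.
2. **Gene-level Bayesian association** (the TADA model family) — for gene
   *g* and variant class *c*, de novo counts over *N* trios are
   Poisson(2*N*·μ<sub>c</sub>·γ) with relative risk γ ~ Gamma(γ̄β, β) under
   the risk hypothesis and γ = 1 under the null, giving the closed-form
   Bayes factor

   BF = e^λ · β^α · Γ(x+α) / (Γ(α) · (λ+β)^{x+α}),  λ = 2Nμ, α = γ̄β.

   Case/control counts share a per-gene variant frequency *q* ~ Gamma(ρ, ν);
   *q* integrates out analytically and γ by deterministic quadrature.
   Per-gene evidence multiplies across classes and arms; posterior
   probabilities use a prior risk-gene fraction π, and the Bayesian FDR
   (q-value) at rank *k* is the running mean of posterior null
   probabilities down the Bayes-factor ranking.
3. **Known/novel cataloguing** — candidates (q < 0.1) merge with the
   X-linked hemizygous genes; a candidate is *known* when it appears in
   curated large-scale study lists, OMIM NDD entries, or SFARI categories
   syndromic/1/2, otherwise *novel*.
4. **Co-expression permutation test** — postnatal cortical expression
   profiles are thresholded at |Pearson r| > 0.7; the observed connectivity
   of novel candidates to known genes (novel genes connected, known genes
   reached, novel–known edges) is compared with random gene sets drawn from
   the expression background, p = (b+1)/(n+1).
5. **Functional network** — protein–protein interactions (confidence score
   ≥ 0.45) and co-expression edges are pooled; known genes enter only when
   they touch ≥ 2 novel seed genes, and membership is tested for gene-set
   over-representation (one-sided hypergeometric).
6. **Constraint analysis** — genome-wide pLI/RVIS percentile ranks, a
   two-tailed Wilcoxon rank-sum comparison (exact by enumeration for small
   samples), and the count of genes in the intolerant top fraction.

A synthetic-data module generates every input the pipeline consumes —
Poisson de novo counts at rate 2Nμ inflated by planted relative risks,
Gamma-Poisson case/control counts, latent-factor co-expression modules,
module-structured PPI graphs with Beta-distributed confidence scores, and
constraint scores correlated with risk status — so the whole analysis is
testable without any download.

## Worked example

Simulate a 2000-trio cohort of 200 panel genes (10 planted risk genes) and
run the full pipeline:

```bash
nddprio simulate --out-dir demo_ws --seed 2 --n-trios 2000
nddprio run-all --workspace demo_ws --out-dir demo_out --seed 2 --n-iter 100000
```

`demo_out/run_report.json` from this exact invocation reports:

* `filter`: 617 of 704 variant rows pass the functional and frequency
  filters across 200 genes.
* `tada`: 6 candidate genes at q < 0.1 (all are planted risk genes;
  `demo_out/catalog.tsv` labels 4 novel and 2 known, e.g. novel G0095 at
  q = 0.0024).
* `coexpr`: 60 postnatal cortical samples give 208 co-expression edges; the
  4 novel candidates show 7 connections to the known reference genes,
  permutation p = 0.0012 (connections), 0.0030 (novel genes connected),
  0.021 (known genes reached) at 100,000 iterations — the planted
  convergence of risk genes in expression modules is recovered.
* `network`: a 7-node, 19-edge seed network; 2 novel candidates remain
  isolated seeds.
* `constraint`: candidates have lower RVIS percentiles than background
  (rank-sum p = 0.010).

Re-running with the same seed and config reproduces every output file
byte-for-byte (hashes are recorded in the run report). Each stage is also
available as its own subcommand (`filter`, `tada`, `catalog`, `coexpr`,
`network`, `constraint`) for real annotated-variant TSVs; see
`nddprio --help`.

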