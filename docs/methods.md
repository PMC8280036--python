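# Methods

## Variant classification

A variant row is one annotated call in one proband: gene symbol, effect
class, ReVe deleteriousness score (missense only), allele frequencies from
up to three population resources, and the trio genotypes. Chromosome names
are normalized to the prefix-free form; X pseudo-autosomal regions are not
treated specially.

Inheritance is purely genotype-based: de novo requires both parents present
and homozygous reference; exactly one carrier parent gives a phased
inherited call; both carriers give `inherited_unphased`; any missing
parental genotype gives `unknown` (the class that singleton probands fall
into). There is no genotype-quality or read-depth modelling — calls are
assumed validated upstream. Rows whose proband does not carry the alternate
allele are malformed and dropped with a warning.

Functional classes: PTV for the four truncating effects; Dmis for missense
with ReVe **strictly above** 0.7 (a score equal to the threshold is
excluded, matching the exclusion rule "ReVe ≤ 0.7"); everything else
excluded. The frequency filter passes a variant iff every *observed*
frequency is ≤ 0.1%; a variant absent from all databases passes, since rare
panel variants are typically unobserved and treating absence as commonness
would discard exactly the variants of interest.

Counting conventions: de novo counts accrue over trio probands;
the case arm pools phased-inherited, unphased and unknown variants over all
probands, so singleton probands contribute through the unknown class (they
were sequenced as cases and their qualifying variants carry case-control
information even without phase). Control counts enter as a separate
per-gene table since controls are not trios. X-linked hemizygous detection
requires a hemizygous proband call on chrX with a heterozygous mother and a
non-carrier father; hemizygous calls with homozygous-reference parents are
de novo and are routed to the de novo counts instead. The recurrent-DNV
table sorts by total de novo count descending, then gene symbol ascending.

## Gene-level Bayesian association

Per gene and variant class c ∈ {PTV, Dmis}:

* **De novo arm.** x ~ Poisson(λγ), λ = 2Nμ_c. Null: γ = 1. Risk:
  γ ~ Gamma(α, β), α = γ̄β. Gamma-Poisson conjugacy gives
  BF = e^λ β^α Γ(x+α) / (Γ(α)(λ+β)^{x+α}), evaluated in log space with
  log-gamma throughout. μ = 0 defines BF = 1 when x = 0 and is an error
  when x > 0 (a count that is impossible under the null).
* **Case-control arm.** q ~ Gamma(ρ, ν) is the per-gene qualifying-variant
  frequency; x_ctrl ~ Poisson(n_ctrl·q), x_case ~ Poisson(n_case·q·γ) with
  γ = 1 (null) or γ ~ Gamma(γ̄_cc·β_cc, β_cc) (risk). q integrates out
  analytically; the remaining 1-D expectation over γ is computed by
  adaptive quadrature against the *shifted* density Gamma(α + x_case, β)
  (pulling γ^{x_case} into the prior), on
  (0, (α+x_case)/β + 12√(α+x_case)/β) plus the analytic-range tail to
  infinity, absolute tolerance 1e-10. The shift keeps the stated tolerance
  meaningful when case counts move the integrand's mass to the right of the
  prior's.

Evidence multiplies across classes and arms in log space; an absent arm
contributes factor 1. Posterior probability pp = πBF/(πBF + 1 − π) with
prior risk fraction π. The Bayesian q-value at rank k (genes ordered by BF
descending, ties broken by symbol) is the running mean of (1 − pp) over the
top k, regularized to be non-decreasing down the ranking by a cumulative
maximum (the raw running mean can dip when a high-pp gene follows lower
ones). The tie-break makes q-values reproducible and invariant to gene
relabelling.

Hyperparameter defaults (all configurable): γ̄_dn = 20 (PTV), 4.7 (Dmis),
β_dn = 1; γ̄_cc = 2.3, β_cc = 4; ρ = 0.1, ν = 200 (mean qualifying
frequency 5×10⁻⁴); π = 0.05. These magnitudes are the conventional ones for
this model family — strong prior relative risk for truncating variants,
weaker for damaging missense, modest case-control risk. No claim is made
that they match any particular study's unpublished settings, which is why
numerical equality with published per-gene FDR values is not a test
surface; threshold-partition counts of published FDR columns are. X-linked
genes use the same λ = 2Nμ as autosomes (no hemizygous male correction).

A two-stage design (own cohort, then cohort plus public datasets) is two
invocations of `prioritize` on two count tables; there is no special-case
code.

## Catalog rules

Known iff any of: membership in a curated publication risk-gene list, an
OMIM NDD association, or SFARI category syndromic/1/2 — the OR-rule taken
literally, with no precedence among sources. "No obvious literature
evidence" is a curated boolean input (`pubmed_support`), not an automated
query; a candidate is novel only when no rule fires *and* that flag is
false. A gene qualifying by FDR and by X-linked inheritance appears once
with both sources, FDR stratum listed first. When two analysis stages both
qualify a gene, the combined-stage stratum is the one reported.

## Co-expression permutation test

Samples are filtered to postnatal cortical before any correlation; genes
with zero variance across the retained samples join no edges (their Pearson
correlation is undefined). Edges require |r| strictly above the threshold
(two-sided: strong negative co-expression counts).

The test fixes the known set and redraws the novel set — uniformly without
replacement from the background, default all graph genes minus known (the
genes that could have been novel). Genes absent from the expression matrix
are dropped from the sets before testing and reported. Three statistics are
computed per draw on the same null sample: novel genes with ≥ 1 edge to
known, known genes with ≥ 1 edge to the drawn set, and the number of
novel–known edges. p = (b+1)/(n+1) (add-one rule, so p is never 0 and the
test is exact-conservative). The default iteration count is 1,000,000;
tests and the demo use smaller counts, exposed as a parameter. Internally
the null loop is vectorized with bit-packed known-adjacency rows, so a
million iterations on a few hundred genes run in seconds.

## Functional network

The evidence graph is the union of the thresholded PPI graph (score ≥ 0.45,
boundary inclusive; duplicate pairs keep the maximum score; self-loops
dropped) and the co-expression graph, restricted to candidate genes, with
edge provenance `ppi`/`coexpr`/`both`. Known genes are admitted when they
have ≥ 2 novel neighbors in the evidence graph; novel seeds are retained
when they have ≥ 1 evidence edge to an admitted known gene or another novel
gene. Seeds failing that rule are reported separately as isolated rather
than silently dropped. Known–known edges among admitted nodes are kept by
default (`include_known_known=False` restricts to seed-incident edges). The
degree table covers *every* seed gene, showing 0 for isolated ones.
Over-representation uses the one-sided hypergeometric upper tail with a
Haldane 0.5 correction on the odds ratio when any 2×2 cell is zero.

## Constraint percentiles

Percentile = 100·rank/n over the non-missing genes of the supplied
background universe (genome-wide, not the candidate set), average ranks for
ties; pLI ranks descending (pLI ≈ 1 → low percentile → intolerant) and RVIS
ascending. The rank-sum test enumerates all C(n₁+n₂, n₁) assignments
exactly when n₁+n₂ ≤ 12 (ties handled exactly); larger samples use the
normal approximation with tie and continuity corrections. The top-fraction
count judges genes missing one metric on the available one — required so
that a gene scored on pLI alone can still count — and skips genes missing
both.

## Synthetic data

Defaults are the desk-scale study conditions: 200 panel genes, 500 trios
plus 90 singleton probands (590 probands in the case arm) and 1900
controls, mirroring a targeted-panel trio study's roughly 1.2:1
proband:trio and 3.2:1 control:proband structure; 5% planted risk genes
with γ_PTV = 20, γ_Dmis = 4.7, γ_cc = 2.3. Per-gene per-class mutation
rates are log-normal (median 10⁻⁵, σ_log = 0.6 — large brain-expressed
panel genes sit well above the exome-wide average). Qualifying-variant
frequencies are Gamma(0.1, 200). Counts expand into per-proband variant
rows (singletons get missing parental genotypes), plus decoy rows that fail
the functional or frequency filters so the filter stage is exercised. With
`draw_gamma_from_prior=True` the per-gene relative risks are drawn from the
analysis priors, making the Bayesian model exactly the generating model —
the configuration used for FDR-calibration runs, where the realized
false-discovery proportion is compared with binomial bounds rather than
asserted equal to the nominal level.

Expression: genes in a module share a latent factor only in postnatal
cortical samples; the loading is derived from the target within-module
correlation r = λ²/(λ²+σ²) (default 0.8). The workspace generator places
planted risk genes into the modules first, emulating the convergence of
risk genes in brain co-expression modules that the permutation test is
designed to detect. PPI edges are dense within modules (p = 0.8, scores
Beta(8,2), mostly above 0.45) and sparse elsewhere (p = 0.01, Beta(2,8)).
Constraint scores draw pLI from Beta(9,1) and RVIS from N(−1.5, 0.6²) for
risk genes versus Beta(1,3) and N(0.2, 0.8²) for null genes.

Every generator is deterministic given a seed, with draws partitioned per
gene/sample; the workspace generator spawns independent child seeds per
file so each stream is reproducible in isolation, and records the cohort
sizes in `workspace.yaml`.

What the generator does **not** emulate: sequence context and per-gene
length effects on mutation rates, linkage and recurrent sites, batch or
coverage artefacts, realistic expression dynamics across development, and
the heavy-tailed degree distribution of curated interactomes. Passing tests
therefore demonstrate the statistical machinery's correctness and
calibration under the stated model, not robustness to those real-data
complications.

## Numerical and test-design choices

* All probability arithmetic in log space; `log-gamma`/`logit`/`expit`
  throughout.
* Permutation p-value uniformity can only hold when the statistic is
  near-continuous under the null, so the calibration design uses two dense
  50-gene modules (target |r| = 0.75) with 15 known genes in each; the
  connection count then takes many distinct values and the add-one p-values
  are close to uniform. Sparse designs make the statistic (and hence p)
  heavily discrete — a property of permutation tests, not a defect of the
  implementation.
* Quadrature oracles in the tests integrate the same models with generic
  routines (including the tail segments to infinity and a u = q^ρ
  substitution that removes the Gamma(ρ, ν) singularity at 0), with pure
  relative-error targets: absolute targets are meaningless when the
  marginal likelihoods straddle twenty orders of magnitude.
* Problem sizes in tests and the acceptance script (200 genes, 500 trios,
  20 calibration seeds, 2,000-10,000 permutation iterations, 200 KS
  replicates) are chosen so the full suite runs in about a minute on one
  CPU while keeping every statistical check at meaningful power.

## Known limitations

* The case-control arm assumes independent Poisson sampling with a shared
  q; related probands or population structure would violate it.
* Compound-heterozygous and multi-allelic sites are treated as independent
  rows (their joint inheritance is not modelled).
* The permutation background excludes only the known set; selection effects
  from panel design are not modelled.
* The known/novel split depends entirely on the curated evidence table
  supplied; the package ships no gene lists beyond small fixtures.
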