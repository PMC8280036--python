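"""Synthetic cohort, expression, PPI and constraint generators.

Every input the pipeline consumes can be generated here with the statistical
structure the analysis assumes:

* cohort — per-gene mutation rates are log-normal; a fraction of genes are
  planted risk genes whose de novo counts are Poisson(2 * n_trios * mu *
  gamma) and whose case counts are inflated by a case-control relative risk
  acting on a Gamma-distributed per-gene variant frequency q.  Counts are
  expanded into per-proband annotated variant rows (trios plus singleton
  probands with missing parental genotypes), with decoy rows that fail the
  functional or frequency filters.
* expression — genes in a module share a latent factor with loading chosen
  so that the expected within-module |r| matches a configured target;
  metadata mixes prenatal/postnatal and cortical/non-cortical samples, and
  only postnatal cortical samples carry the module structure.
* PPI — dense high-confidence edges within modules, sparse low-confidence
  background edges, scores Beta-distributed on either side of 0.45.
* constraint — risk genes draw pLI near 1 and negative RVIS; null genes
  draw from tolerant distributions.

All generators are deterministic given a seed; draws are partitioned per
gene/sample so adding parameters does not silently shift downstream draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .tada import TadaHyperparams

BASES = ("A", "C", "G", "T")
PTV_EFFECT_CHOICES = ("frameshift", "stop_gain", "splicing", "stop_loss")


@dataclass
class SimulationConfig:
    """Defaults are the desk-scale study conditions: 200 panel genes,
    500 trios plus 90 singleton probands (so 590 probands in the case arm,
    mirroring the roughly 1.2:1 proband:trio and 3.2:1 control:proband
    structure of a targeted-panel trio study), strong truncating-variant
    relative risk at 5% planted risk genes."""

    n_genes: int = 200
    n_trios: int = 500
    n_singletons: int = 90
    n_controls: int = 1900
    risk_fraction: float = 0.05
    gamma_dn: dict[str, float] = field(default_factory=lambda: {"PTV": 20.0, "Dmis": 4.7})
    gamma_cc: float = 2.3
    draw_gamma_from_prior: bool = False  # draw per-gene gammas from the analysis priors
    mu_meanlog: float = float(np.log(1e-5))  # per-class de novo rate, log-normal
    mu_sdlog: float = 0.6
    rho: float = 0.1  # Gamma prior shape for per-gene variant frequency q
    nu: float = 200.0  # Gamma prior rate (mean q = rho/nu = 5e-4)
    decoy_rate: float = 0.5  # expected filtered-out rows per gene
    # expression
    n_samples: int = 100
    n_postnatal_cortical: int = 60
    n_modules: int = 5
    module_size: int = 10
    module_r: float = 0.8  # target expected within-module |Pearson r|
    # PPI
    ppi_p_within: float = 0.8
    ppi_p_background: float = 0.01
    miscore_within: tuple[float, float] = (8.0, 2.0)  # Beta params, mass above 0.45
    miscore_background: tuple[float, float] = (2.0, 8.0)
    # constraint
    pli_risk: tuple[float, float] = (9.0, 1.0)
    pli_null: tuple[float, float] = (1.0, 3.0)
    rvis_risk: tuple[float, float] = (-1.5, 0.6)  # Normal(mean, sd)
    rvis_null: tuple[float, float] = (0.2, 0.8)

    def __post_init__(self) -> None:
        if not 0.0 <= self.risk_fraction <= 1.0:
            raise ValueError("risk_fraction outside [0,1]")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("module genes exceed n_genes")
        if self.n_postnatal_cortical > self.n_samples:
            raise ValueError("n_postnatal_cortical exceeds n_samples")
        for n in (self.n_genes, self.n_trios, self.n_samples):
            if n <= 0:
                raise ValueError("sizes must be positive")


def gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


@dataclass
class CohortSim:
    variants: pd.DataFrame  # annotated-variant TSV dialect, one row per proband variant
    mutation_rates: pd.DataFrame  # gene x (mu_PTV, mu_Dmis)
    control_counts: pd.DataFrame  # gene x (ctrl_PTV, ctrl_Dmis)
    truth: pd.DataFrame  # gene, is_risk, gamma per class, q per class


def _variant_row(
    rng: np.random.Generator,
    gene: str,
    family: str,
    cls: str,
    inherited: str,  # "de_novo" | "inherited" | "unknown"
    i: int,
) -> dict:
    ref, alt = rng.choice(BASES, size=2, replace=False)
    if cls == "PTV":
        effect = str(rng.choice(PTV_EFFECT_CHOICES))
        reve = None
    else:
        effect = "missense"
        reve = float(rng.uniform(0.705, 1.0))
    af = 0.0 if rng.random() < 0.7 else float(rng.uniform(0.0, 5e-4))
    if inherited == "de_novo":
        gt_f, gt_m = "hom_ref", "hom_ref"
    elif inherited == "unknown":
        gt_f, gt_m = "missing", "missing"
    else:
        if rng.random() < 0.5:
            gt_f, gt_m = "het", "hom_ref"
        else:
            gt_f, gt_m = "hom_ref", "het"
    return {
        "family_id": family,
        "sample_role": "proband",
        "chrom": str(int(rng.integers(1, 23))),
        "pos": int(rng.integers(1, 10_000_000)),
        "ref": str(ref),
        "alt": str(alt),
        "gene": gene,
        "effect": effect,
        "reve": reve,
        "af_gnomad": af,
        "af_exac": None if rng.random() < 0.5 else af,
        "af_inhouse": 0.0,
        "gt_proband": "het",
        "gt_father": gt_f,
        "gt_mother": gt_m,
        "proband_sex": str(rng.choice(["male", "female"])),
    }


def _decoy_row(rng: np.random.Generator, gene: str, family: str, i: int) -> dict:
    row = _variant_row(rng, gene, family, "Dmis", "de_novo", i)
    kind = rng.random()
    if kind < 0.4:
        row["effect"] = "other"
        row["reve"] = None
    elif kind < 0.7:
        row["effect"] = "missense"
        row["reve"] = float(rng.uniform(0.0, 0.7))
    else:
        row["af_gnomad"] = float(rng.uniform(0.005, 0.05))  # too common
    return row


def simulate_cohort(
    cfg: SimulationConfig, seed: int | None = None, params: TadaHyperparams | None = None
) -> CohortSim:
    """Generate the variant table, mutation rates, control counts and truth.

    With ``cfg.draw_gamma_from_prior`` the per-gene relative risks are drawn
    from the analysis priors (``params``), so the Bayesian model is exactly
    the generating model — the configuration used for FDR-calibration runs.
    """
    rng = np.random.default_rng(seed)
    params = params or TadaHyperparams()
    genes = gene_names(cfg.n_genes)
    n_risk = int(round(cfg.risk_fraction * cfg.n_genes))
    is_risk = np.zeros(cfg.n_genes, dtype=bool)
    risk_idx = rng.choice(cfg.n_genes, size=n_risk, replace=False)
    is_risk[risk_idx] = True

    mu = {
        cls: np.exp(rng.normal(cfg.mu_meanlog, cfg.mu_sdlog, size=cfg.n_genes))
        for cls in ("PTV", "Dmis")
    }
    gamma = {}
    for cls in ("PTV", "Dmis"):
        g = np.ones(cfg.n_genes)
        if cfg.draw_gamma_from_prior:
            a = params.gamma_bar_dn[cls] * params.beta_dn[cls]
            g[is_risk] = rng.gamma(a, 1.0 / params.beta_dn[cls], size=n_risk)
        else:
            g[is_risk] = cfg.gamma_dn[cls]
        gamma[cls] = g
    gamma_cc = {}
    for cls in ("PTV", "Dmis"):
        g = np.ones(cfg.n_genes)
        if cfg.draw_gamma_from_prior:
            a = params.gamma_bar_cc[cls] * params.beta_cc[cls]
            g[is_risk] = rng.gamma(a, 1.0 / params.beta_cc[cls], size=n_risk)
        else:
            g[is_risk] = cfg.gamma_cc
        gamma_cc[cls] = g

    n_cases = cfg.n_trios + cfg.n_singletons
    q = {
        cls: rng.gamma(cfg.rho, 1.0 / cfg.nu, size=cfg.n_genes) for cls in ("PTV", "Dmis")
    }
    rows: list[dict] = []
    ctrl = pd.DataFrame(0, index=pd.Index(genes, name="gene"), columns=["ctrl_PTV", "ctrl_Dmis"])
    for gi, gene in enumerate(genes):
        for cls in ("PTV", "Dmis"):
            lam_dn = 2.0 * cfg.n_trios * mu[cls][gi] * gamma[cls][gi]
            for i in range(rng.poisson(lam_dn)):
                fam = f"F{int(rng.integers(1, cfg.n_trios + 1)):05d}"
                rows.append(_variant_row(rng, gene, fam, cls, "de_novo", i))
            x_case = rng.poisson(n_cases * q[cls][gi] * gamma_cc[cls][gi])
            for i in range(x_case):
                singleton = rng.random() < cfg.n_singletons / n_cases
                fam = (
                    f"S{int(rng.integers(1, cfg.n_singletons + 1)):05d}"
                    if singleton
                    else f"F{int(rng.integers(1, cfg.n_trios + 1)):05d}"
                )
                rows.append(
                    _variant_row(rng, gene, fam, cls, "unknown" if singleton else "inherited", i)
                )
            ctrl.loc[gene, f"ctrl_{cls}"] = rng.poisson(cfg.n_controls * q[cls][gi])
        for i in range(rng.poisson(cfg.decoy_rate)):
            fam = f"F{int(rng.integers(1, cfg.n_trios + 1)):05d}"
            rows.append(_decoy_row(rng, gene, fam, i))

    variants = pd.DataFrame(rows)
    if len(variants):
        variants.insert(0, "variant_id", [f"v{i:06d}" for i in range(1, len(variants) + 1)])
    else:
        variants = pd.DataFrame(
            columns=["variant_id", "family_id", "sample_role", "chrom", "pos", "ref", "alt",
                     "gene", "effect", "reve", "af_gnomad", "af_exac", "af_inhouse",
                     "gt_proband", "gt_father", "gt_mother", "proband_sex"]
        )
    mutation_rates = pd.DataFrame(
        {"mu_PTV": mu["PTV"], "mu_Dmis": mu["Dmis"]}, index=pd.Index(genes, name="gene")
    )
    truth = pd.DataFrame(
        {
            "is_risk": is_risk,
            "gamma_dn_PTV": gamma["PTV"],
            "gamma_dn_Dmis": gamma["Dmis"],
            "gamma_cc_PTV": gamma_cc["PTV"],
            "gamma_cc_Dmis": gamma_cc["Dmis"],
            "q_PTV": q["PTV"],
            "q_Dmis": q["Dmis"],
        },
        index=pd.Index(genes, name="gene"),
    )
    return CohortSim(variants, mutation_rates, ctrl, truth)


@dataclass
class ExpressionSim:
    values: pd.DataFrame  # genes x samples
    metadata: pd.DataFrame  # sample x (stage, region, cortical)
    module_map: pd.DataFrame  # gene -> module id (-1 for none), expected |r|


def simulate_expression(
    cfg: SimulationConfig,
    seed: int | None = None,
    module_genes: list[str] | None = None,
) -> ExpressionSim:
    """Latent-factor module structure in postnatal cortical samples.

    For genes g, h in the same module observed in samples carrying the
    factor, corr(x_g, x_h) = loading^2 / (loading^2 + sigma^2); sigma is
    derived from the configured target ``module_r``.  ``module_genes``
    fills the module slots first (the workspace generator passes the
    planted risk genes here, emulating the convergence of risk genes in
    brain co-expression modules); remaining slots are filled in gene order.
    """
    rng = np.random.default_rng(seed)
    genes = gene_names(cfg.n_genes)
    samples = [f"S{i:03d}" for i in range(1, cfg.n_samples + 1)]
    n_pc = cfg.n_postnatal_cortical
    stage = np.array(["postnatal"] * n_pc + ["prenatal"] * (cfg.n_samples - n_pc))
    cortical = np.array([True] * n_pc + [False] * (cfg.n_samples - n_pc))
    # a few postnatal non-cortical samples so the filter is non-trivial on both axes
    n_post_noncort = min(5, cfg.n_samples - n_pc)
    stage[n_pc : n_pc + n_post_noncort] = "postnatal"
    region = np.where(cortical, "cortex", "cerebellum")
    metadata = pd.DataFrame(
        {"stage": stage, "region": region, "cortical": cortical},
        index=pd.Index(samples, name="sample"),
    )

    module = np.full(cfg.n_genes, -1, dtype=int)
    gene_pos = {g: i for i, g in enumerate(genes)}
    priority = [g for g in (module_genes or []) if g in gene_pos]
    fill_order = priority + [g for g in genes if g not in set(priority)]
    for slot, gene in enumerate(fill_order[: cfg.n_modules * cfg.module_size]):
        module[gene_pos[gene]] = slot // cfg.module_size

    loading = 1.0
    if not 0.0 <= cfg.module_r < 1.0:
        raise ValueError("module_r must be in [0,1)")
    sigma = (
        np.sqrt(loading**2 * (1.0 - cfg.module_r) / cfg.module_r) if cfg.module_r > 0 else 1.0
    )
    if cfg.module_r == 0:
        loading = 0.0

    x = rng.normal(0.0, sigma if cfg.module_r > 0 else 1.0, size=(cfg.n_genes, cfg.n_samples))
    factors = rng.normal(0.0, 1.0, size=(cfg.n_modules, cfg.n_samples))
    pc_mask = (metadata["stage"] == "postnatal") & metadata["cortical"]
    pc_cols = np.flatnonzero(pc_mask.to_numpy())
    for gi in range(cfg.n_genes):
        if module[gi] >= 0 and loading > 0:
            x[gi, pc_cols] += loading * factors[module[gi], pc_cols]
    x += rng.normal(5.0, 1.0, size=(cfg.n_genes, 1))  # per-gene baseline level

    values = pd.DataFrame(x, index=pd.Index(genes, name="gene"), columns=samples)
    module_map = pd.DataFrame(
        {
            "module": module,
            "expected_abs_r": np.where(module >= 0, cfg.module_r, 0.0),
        },
        index=pd.Index(genes, name="gene"),
    )
    return ExpressionSim(values, metadata, module_map)


def simulate_ppi(
    cfg: SimulationConfig, module_map: pd.DataFrame, seed: int | None = None
) -> pd.DataFrame:
    """Edge list (gene_a, gene_b, miscore): dense confident edges within
    modules, sparse low-confidence background edges."""
    rng = np.random.default_rng(seed)
    genes = list(module_map.index)
    module = module_map["module"].to_numpy()
    rows = []
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            same = module[i] >= 0 and module[i] == module[j]
            p = cfg.ppi_p_within if same else cfg.ppi_p_background
            if rng.random() < p:
                a, b = (cfg.miscore_within if same else cfg.miscore_background)
                rows.append(
                    {"gene_a": genes[i], "gene_b": genes[j], "miscore": float(rng.beta(a, b))}
                )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "miscore"])


def simulate_constraint(
    truth: pd.DataFrame, cfg: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """pLI/RVIS scores correlated with planted risk status."""
    rng = np.random.default_rng(seed)
    is_risk = truth["is_risk"].to_numpy(dtype=bool)
    n = len(truth)
    pli = np.where(
        is_risk,
        rng.beta(*cfg.pli_risk, size=n),
        rng.beta(*cfg.pli_null, size=n),
    )
    rvis = np.where(
        is_risk,
        rng.normal(*cfg.rvis_risk, size=n),
        rng.normal(*cfg.rvis_null, size=n),
    )
    return pd.DataFrame({"pli": pli, "rvis": rvis}, index=truth.index)


def simulate_evidence(
    truth: pd.DataFrame, seed: int | None = None, known_fraction: float = 0.5
) -> pd.DataFrame:
    """Evidence table marking a fraction of planted risk genes as established
    candidates (so the catalog stage splits candidates into known and novel)."""
    rng = np.random.default_rng(seed)
    risk_genes = list(truth.index[truth["is_risk"]])
    n_known = int(round(known_fraction * len(risk_genes)))
    known = set(rng.choice(risk_genes, size=n_known, replace=False)) if n_known else set()
    return pd.DataFrame(
        {
            "publications": ["study1" if g in known else "." for g in truth.index],
            "omim_ndd": [int(g in known) for g in truth.index],
            "sfari_category": ["1" if g in known else "none" for g in truth.index],
            "pubmed_support": [int(g in known) for g in truth.index],
        },
        index=truth.index,
    )


def simulate_workspace(
    cfg: SimulationConfig, out_dir: str | Path, seed: int | None = None
) -> dict[str, Path]:
    """Write a complete demo workspace of TSV inputs; returns the file map.

    Sub-generators get independent child seeds from one spawned sequence so
    each stream is reproducible in isolation.
    """
    from . import io as nio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]
    cohort = simulate_cohort(cfg, seed=seeds[0])
    risk_genes = list(cohort.truth.index[cohort.truth["is_risk"]])
    expr = simulate_expression(cfg, seed=seeds[1], module_genes=risk_genes)
    ppi = simulate_ppi(cfg, expr.module_map, seed=seeds[2])
    constraint = simulate_constraint(cohort.truth, cfg, seed=seeds[3])
    evidence = simulate_evidence(cohort.truth, seed=seeds[4])

    paths = {
        "variants": out / "variants.tsv",
        "mutation_rates": out / "mutation_rates.tsv",
        "control_counts": out / "control_counts.tsv",
        "truth": out / "truth.tsv",
        "expression": out / "expression.tsv",
        "sample_metadata": out / "sample_metadata.tsv",
        "module_map": out / "module_map.tsv",
        "ppi": out / "ppi.tsv",
        "constraint": out / "constraint.tsv",
        "evidence": out / "evidence.tsv",
    }
    nio.write_variants(cohort.variants, paths["variants"])
    nio.write_table(cohort.mutation_rates, paths["mutation_rates"])
    nio.write_table(cohort.control_counts, paths["control_counts"])
    nio.write_table(cohort.truth, paths["truth"])
    nio.write_table(expr.values.round(6), paths["expression"])
    nio.write_table(expr.metadata, paths["sample_metadata"])
    nio.write_table(expr.module_map, paths["module_map"])
    nio.write_table(ppi.round(6), paths["ppi"], index=False)
    nio.write_table(constraint.round(6), paths["constraint"])
    nio.write_table(evidence, paths["evidence"])

    import yaml

    sizes = {
        "n_trios": cfg.n_trios,
        "n_cases": cfg.n_trios + cfg.n_singletons,
        "n_controls": cfg.n_controls,
    }
    paths["workspace_meta"] = out / "workspace.yaml"
    with open(paths["workspace_meta"], "w") as fh:
        yaml.safe_dump(sizes, fh, sort_keys=True)
    return paths
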