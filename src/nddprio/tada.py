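"""Gene-level Bayesian association from de novo and case-control counts.

The model follows the transmission-and-de-novo association (TADA) framework.
For each gene and variant class c (PTV, Dmis):

* de novo arm — counts over N trios are Poisson with null rate
  ``lambda = 2 * N * mu_c``; under the risk hypothesis the rate is inflated
  by a relative risk ``gamma ~ Gamma(alpha, beta)`` with prior mean
  ``gamma_bar = alpha / beta``.  Gamma-Poisson conjugacy gives the closed
  form

      BF = exp(lambda) * beta**alpha * G(x + alpha)
           / (G(alpha) * (lambda + beta)**(x + alpha))

  where G is the gamma function; everything is evaluated in log space.

* case-control arm — per-gene qualifying-variant frequency
  ``q ~ Gamma(rho, nu)``; control counts are Poisson(n_ctrl * q) and case
  counts Poisson(n_case * q * gamma) with gamma = 1 under the null and
  ``gamma ~ Gamma(gamma_bar_cc * beta_cc, beta_cc)`` under the alternative.
  q integrates out analytically; gamma is integrated by deterministic
  adaptive quadrature.

Per-gene evidence multiplies across classes and arms.  Posterior
probabilities use a prior fraction pi of risk genes, and a Bayesian FDR
(q-value) is the running mean of posterior null probabilities down the
Bayes-factor ranking, made monotone by a cumulative maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.special import expit, gammaln, logit

from .variants import GeneCountTable

CLASSES = ("PTV", "Dmis")


class QuadratureError(RuntimeError):
    """Numerical integration failed to reach tolerance."""


@dataclass
class TadaHyperparams:
    """Prior hyperparameters, per variant class.

    The study these defaults serve did not publish its values; magnitudes
    are the conventional ones for this model family (strong prior relative
    risk for truncating variants, weaker for damaging missense, modest
    case-control risk with an informative rate prior) and every field is
    exposed in the pipeline configuration.
    """

    gamma_bar_dn: dict[str, float] = field(default_factory=lambda: {"PTV": 20.0, "Dmis": 4.7})
    beta_dn: dict[str, float] = field(default_factory=lambda: {"PTV": 1.0, "Dmis": 1.0})
    gamma_bar_cc: dict[str, float] = field(default_factory=lambda: {"PTV": 2.3, "Dmis": 2.3})
    beta_cc: dict[str, float] = field(default_factory=lambda: {"PTV": 4.0, "Dmis": 4.0})
    rho: dict[str, float] = field(default_factory=lambda: {"PTV": 0.1, "Dmis": 0.1})
    nu: dict[str, float] = field(default_factory=lambda: {"PTV": 200.0, "Dmis": 200.0})
    pi: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError(f"pi={self.pi} outside (0,1)")
        for name in ("gamma_bar_dn", "beta_dn", "gamma_bar_cc", "beta_cc", "rho", "nu"):
            for c, val in getattr(self, name).items():
                if val <= 0:
                    raise ValueError(f"{name}[{c}]={val} must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "TadaHyperparams":
        """Build from a (possibly partial) plain mapping, e.g. parsed YAML."""
        kw: dict = {}
        base = cls()
        for name in ("gamma_bar_dn", "beta_dn", "gamma_bar_cc", "beta_cc", "rho", "nu"):
            if name in d:
                v = d[name]
                kw[name] = dict(v) if isinstance(v, dict) else {c: float(v) for c in CLASSES}
            else:
                kw[name] = getattr(base, name)
        kw["pi"] = float(d.get("pi", base.pi))
        return cls(**kw)


def log_dn_bayes_factor(
    x: int, n_trios: int, mu: float, gamma_bar: float, beta: float
) -> float:
    """Log Bayes factor for a de novo count (closed form, log space)."""
    if x < 0 or x != int(x):
        raise ValueError(f"de novo count must be a non-negative integer, got {x}")
    if mu < 0:
        raise ValueError(f"mutation rate must be >= 0, got {mu}")
    x = int(x)
    if mu == 0.0:
        if x == 0:
            return 0.0
        raise ValueError(f"impossible count under null: x={x} with mu=0")
    lam = 2.0 * n_trios * mu
    alpha = gamma_bar * beta
    return (
        lam
        + alpha * math.log(beta)
        + gammaln(x + alpha)
        - gammaln(alpha)
        - (x + alpha) * math.log(lam + beta)
    )


def dn_bayes_factor(x: int, n_trios: int, mu: float, gamma_bar: float, beta: float) -> float:
    return float(np.exp(log_dn_bayes_factor(x, n_trios, mu, gamma_bar, beta)))


def log_cc_bayes_factor(
    x_case: int,
    x_ctrl: int,
    n_case: int,
    n_ctrl: int,
    gamma_bar: float,
    beta: float,
    rho: float,
    nu: float,
    gene: str | None = None,
    abs_tol: float = 1e-10,
) -> float:
    """Log Bayes factor for case/control counts.

    q is integrated analytically; the ratio reduces to a 1-D expectation over
    the relative risk.  Writing T = x_case + x_ctrl and s = n_case + n_ctrl:

        BF = E_{gamma ~ Gamma(alpha + x_case, beta)} [
                 ((s + nu) / (n_ctrl + n_case * gamma + nu)) ** (T + rho) ]
             * G(alpha + x_case) / (G(alpha) * beta**x_case)

    which follows from pulling gamma**x_case into the Gamma density.  The
    expectation is computed by adaptive quadrature on a range wide enough to
    cover the shifted density's mass.
    """
    if min(x_case, x_ctrl) < 0 or x_case != int(x_case) or x_ctrl != int(x_ctrl):
        raise ValueError("case/control counts must be non-negative integers")
    if n_case <= 0 or n_ctrl <= 0:
        raise ValueError("cohort sizes must be positive")
    alpha = gamma_bar * beta
    total = x_case + x_ctrl
    s = n_case + n_ctrl
    a_post = alpha + x_case

    log_num = (total + rho) * math.log(s + nu)
    log_norm = a_post * math.log(beta) - gammaln(a_post)  # Gamma(a_post, beta) density constant

    def integrand(g: float) -> float:
        if g <= 0.0:
            return 0.0
        log_f = (
            log_norm
            + (a_post - 1.0) * math.log(g)
            - beta * g
            + log_num
            - (total + rho) * math.log(n_ctrl + n_case * g + nu)
        )
        return math.exp(log_f)

    upper = a_post / beta + 12.0 * math.sqrt(a_post) / beta + 1.0
    val, err = quad(integrand, 0.0, upper, epsabs=abs_tol, epsrel=1e-10, limit=200)
    tail, terr = quad(integrand, upper, np.inf, epsabs=abs_tol, epsrel=1e-8, limit=200)
    val += tail
    if val <= 0.0 or err + terr > max(abs_tol, 1e-6 * val):
        raise QuadratureError(
            f"case-control quadrature did not converge{' for gene ' + gene if gene else ''}"
        )
    log_pref = gammaln(a_post) - gammaln(alpha) - x_case * math.log(beta)
    return log_pref + math.log(val)


def cc_bayes_factor(
    x_case: int,
    x_ctrl: int,
    n_case: int,
    n_ctrl: int,
    params: TadaHyperparams,
    cls: str,
    gene: str | None = None,
) -> float:
    return float(
        np.exp(
            log_cc_bayes_factor(
                x_case,
                x_ctrl,
                n_case,
                n_ctrl,
                gamma_bar=params.gamma_bar_cc[cls],
                beta=params.beta_cc[cls],
                rho=params.rho[cls],
                nu=params.nu[cls],
                gene=gene,
            )
        )
    )


def combine_evidence(
    bf_dn: dict[str, float] | None = None, bf_cc: dict[str, float] | None = None
) -> float:
    """Total Bayes factor: product over classes and arms, in log space.
    Absent arms contribute a factor of 1."""
    factors = list((bf_dn or {}).values()) + list((bf_cc or {}).values())
    if any(f < 0 for f in factors):
        raise ValueError("Bayes factors must be non-negative")
    if any(f == 0.0 for f in factors):
        return 0.0
    return float(np.exp(sum(math.log(f) for f in factors)))


def bayesian_qvalues(bf_total: pd.Series, pi: float) -> pd.DataFrame:
    """Posterior probabilities and Bayesian FDR q-values from total BFs.

    pp = pi*BF / (pi*BF + 1 - pi).  Genes are ranked by BF descending (ties
    broken by gene symbol ascending); the q-value at rank k is the running
    mean of (1 - pp) over the top k, regularized to be non-decreasing down
    the ranking by a cumulative maximum.
    """
    if not 0.0 < pi < 1.0:
        raise ValueError(f"pi={pi} outside (0,1)")
    with np.errstate(divide="ignore"):
        log_bf = np.log(bf_total.to_numpy(dtype=float))
    pp = pd.Series(expit(log_bf + logit(pi)), index=bf_total.index)
    order = (
        pd.DataFrame({"bf": bf_total.to_numpy(), "symbol": list(bf_total.index)})
        .sort_values(["bf", "symbol"], ascending=[False, True])["symbol"]
        .to_list()
    )
    pp_sorted = pp.loc[order]
    running = (1.0 - pp_sorted).expanding().mean()
    q_sorted = running.cummax()
    out = pd.DataFrame({"pp": pp, "qvalue": q_sorted.reindex(pp.index)})
    return out


def prioritize(
    counts: GeneCountTable,
    mutation_rates: pd.DataFrame,
    params: TadaHyperparams | None = None,
    fdr_threshold: float = 0.1,
    include_cc: bool = True,
) -> pd.DataFrame:
    """Full gene table: per-class Bayes factors, combined BF, posterior
    probability, Bayesian q-value and candidate flag at the FDR threshold.

    ``mutation_rates`` is indexed by gene with columns mu_PTV, mu_Dmis.  The
    case-control arm is skipped (factor 1) when ``include_cc`` is false or a
    cohort arm is empty.  Output ordered by q-value then gene symbol.
    """
    params = params or TadaHyperparams()
    genes = counts.genes
    missing = [g for g in genes if g not in mutation_rates.index]
    if missing:
        raise KeyError(f"genes missing from mutation-rate table: {', '.join(sorted(missing))}")
    use_cc = include_cc and counts.n_cases > 0 and counts.n_controls > 0

    rows = []
    for gene in genes:
        rec = counts.counts.loc[gene]
        row: dict[str, float | str | bool] = {"gene": gene}
        log_total = 0.0
        for cls in CLASSES:
            log_dn = log_dn_bayes_factor(
                int(rec[f"dn_{cls}"]),
                counts.n_trios,
                float(mutation_rates.loc[gene, f"mu_{cls}"]),
                params.gamma_bar_dn[cls],
                params.beta_dn[cls],
            )
            row[f"bf_dn_{cls}"] = float(np.exp(log_dn))
            log_total += log_dn
            if use_cc:
                log_cc = log_cc_bayes_factor(
                    int(rec[f"case_{cls}"]),
                    int(rec[f"ctrl_{cls}"]),
                    counts.n_cases,
                    counts.n_controls,
                    gamma_bar=params.gamma_bar_cc[cls],
                    beta=params.beta_cc[cls],
                    rho=params.rho[cls],
                    nu=params.nu[cls],
                    gene=gene,
                )
                row[f"bf_cc_{cls}"] = float(np.exp(log_cc))
                log_total += log_cc
            else:
                row[f"bf_cc_{cls}"] = 1.0
        row["bf_total"] = float(np.exp(log_total))
        rows.append(row)

    df = pd.DataFrame(rows).set_index("gene")
    pq = bayesian_qvalues(df["bf_total"], params.pi)
    df["pp"] = pq["pp"]
    df["qvalue"] = pq["qvalue"]
    df["candidate"] = df["qvalue"] < fdr_threshold
    df = (
        df.assign(_gene=df.index)
        .sort_values(["qvalue", "_gene"], ascending=[True, True])
        .drop(columns="_gene")
    )
    return df
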