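"""Gene-constraint percentiles (pLI, RVIS) and rank-based set comparison.

Percentile ranks are computed over a supplied background universe: pLI is
ranked descending (pLI near 1 -> low percentile, i.e. most intolerant) and
RVIS ascending (most negative -> low percentile).  Gene sets are compared
with a two-tailed Wilcoxon/Mann-Whitney rank-sum test, exact by enumeration
for small samples and by the tie- and continuity-corrected normal
approximation otherwise.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

EXACT_LIMIT = 12  # total sample size up to which the exact null is enumerated


def percentile_ranks(records: pd.DataFrame) -> pd.DataFrame:
    """Add pli_percentile / rvis_percentile columns (in (0, 100]).

    ``records`` is indexed by gene with numeric ``pli`` and ``rvis`` columns;
    missing scores (NaN) yield missing percentiles.  Percentile = 100 * rank
    / n over non-missing genes, with average ranks for ties.
    """
    out = records.copy()
    for col, ascending in (("pli", False), ("rvis", True)):
        vals = out[col].to_numpy(dtype=float)
        mask = ~np.isnan(vals)
        if not mask.any():
            raise ValueError(f"all {col} scores missing: cannot rank")
        ranks = rankdata(vals[mask] if ascending else -vals[mask], method="average")
        pct = np.full(len(out), np.nan)
        pct[mask] = 100.0 * ranks / mask.sum()
        out[f"{col}_percentile"] = pct
    return out


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    ranks = rankdata(np.concatenate([a, b]), method="average")
    r_a = ranks[: len(a)].sum()
    return r_a - len(a) * (len(a) + 1) / 2.0


def rank_sum_test(a, b) -> tuple[float, float]:
    """Mann-Whitney U (for sample ``a``) and two-sided p-value.

    Exact by enumerating all rank assignments when len(a)+len(b) <=
    ``EXACT_LIMIT`` (handles ties exactly); otherwise the normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both samples must be non-empty")
    u_obs = _u_statistic(a, b)
    n1, n2 = len(a), len(b)
    if n1 + n2 <= EXACT_LIMIT:
        pooled = np.concatenate([a, b])
        mean_u = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mean_u)
        total = comb(n1 + n2, n1)
        hits = 0
        idx_all = range(n1 + n2)
        for pick in combinations(idx_all, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(pick)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u - mean_u) >= dev_obs - 1e-12:
                hits += 1
        return float(u_obs), hits / total
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def top_fraction_count(records: pd.DataFrame, cutoff_percentile: float = 50.0) -> int:
    """Number of genes whose every available percentile is <= the cutoff.

    Genes missing one metric are judged on the available one; genes missing
    both metrics are not counted.
    """
    pli = records.get("pli_percentile")
    rvis = records.get("rvis_percentile")
    count = 0
    for gene in records.index:
        vals = []
        for series in (pli, rvis):
            if series is not None and not np.isnan(series.loc[gene]):
                vals.append(float(series.loc[gene]))
        if vals and all(v <= cutoff_percentile for v in vals):
            count += 1
    return count
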