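"""Small reference tables shipped with the package.

These are the study cohort's published per-gene tabulations: the genes with
multiple de novo variants (de novo PTV/Dmis counts plus genome-wide RVIS and
pLI scores and percentiles), and the novel candidate genes with their
Bayesian FDR values.  They serve as regression fixtures and demo inputs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .variants import GeneCountTable


def _read(name: str) -> pd.DataFrame:
    with resources.files("nddprio.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0, na_values=["."])


def load_multi_dnv_table() -> pd.DataFrame:
    """Per-gene de novo PTV/Dmis counts and constraint percentiles for the
    cohort's recurrently mutated genes."""
    return _read("cohort_multi_dnv_genes.tsv")


def load_multi_dnv_counts(
    n_trios: int = 935, n_cases: int = 1102, n_controls: int = 3582
) -> GeneCountTable:
    """The same tabulation as a :class:`GeneCountTable` (cohort sizes default
    to the study's: 935 trios, 1102 probands, 3582 controls)."""
    df = load_multi_dnv_table()[["dn_PTV", "dn_Dmis"]].copy()
    return GeneCountTable(df, n_trios=n_trios, n_cases=n_cases, n_controls=n_controls)


def load_novel_candidate_fdr() -> pd.DataFrame:
    """Novel candidate genes with combined-analysis Bayesian FDR values."""
    return _read("cohort_novel_candidates.tsv")
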