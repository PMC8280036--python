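"""Known/novel classification of candidate genes and candidate-set merging.

A gene is *known* if it is a reported risk gene in any of the curated
large-scale sequencing studies, is an OMIM neurodevelopmental-disorder gene,
or sits in SFARI category syndromic/1/2.  The final candidate set is the
union of the Bayesian-FDR candidates and the genes carrying inherited
X-linked hemizygous variants; candidates with no known-gene evidence and no
curated literature support are labelled *novel*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

KNOWN_SFARI_CATEGORIES = frozenset({"syndromic", "1", "2"})


class CandidateSource(str, Enum):
    tada_fdr_lt_0_05 = "tada_fdr_lt_0.05"
    tada_fdr_0_05_to_0_1 = "tada_fdr_0.05_to_0.1"
    xlinked_hemizygous = "xlinked_hemizygous"
    none = "none"


@dataclass(frozen=True)
class EvidenceRecord:
    """Curated evidence that a gene is already an established candidate."""

    gene: str
    in_publication_lists: frozenset[str] = frozenset()
    omim_ndd: bool = False
    sfari_category: str = "none"
    pubmed_support: bool = False


EMPTY_EVIDENCE = EvidenceRecord(gene="")


@dataclass(frozen=True)
class CatalogEntry:
    gene: str
    status: str  # "known" | "novel"
    sources: tuple[CandidateSource, ...]
    qvalue: float | None = None

    @property
    def source(self) -> CandidateSource:
        """First-listed source, used for single-column reporting."""
        return self.sources[0] if self.sources else CandidateSource.none


def classify_gene(gene: str, ev: EvidenceRecord | None) -> bool:
    """True iff the gene is a known candidate by the evidence OR-rule."""
    if ev is None:
        return False
    return bool(
        ev.in_publication_lists
        or ev.omim_ndd
        or str(ev.sfari_category) in KNOWN_SFARI_CATEGORIES
    )


def merge_candidates(
    tada_results: pd.DataFrame,
    xlinked_genes: Iterable[str],
    evidence: Mapping[str, EvidenceRecord],
    fdr_threshold: float = 0.1,
    fdr_strong: float = 0.05,
) -> list[CatalogEntry]:
    """Union of FDR candidates and X-linked hemizygous genes, deduplicated,
    each labelled known/novel.

    ``tada_results`` is the prioritization table (indexed by gene, with a
    ``qvalue`` column).  A gene qualifying both by FDR and by hemizygous
    inheritance appears once with both sources recorded, FDR stratum first.
    Novel requires that no known-gene rule fires *and* there is no curated
    literature support for an association.
    """
    xlinked = set(xlinked_genes)
    entries: dict[str, tuple[list[CandidateSource], float | None]] = {}
    qv = tada_results["qvalue"]
    for gene in tada_results.index[qv < fdr_threshold]:
        q = float(qv.loc[gene])
        stratum = (
            CandidateSource.tada_fdr_lt_0_05
            if q < fdr_strong
            else CandidateSource.tada_fdr_0_05_to_0_1
        )
        entries[gene] = ([stratum], q)
    for gene in sorted(xlinked):
        if gene in entries:
            entries[gene][0].append(CandidateSource.xlinked_hemizygous)
        else:
            entries[gene] = ([CandidateSource.xlinked_hemizygous], None)

    catalog: list[CatalogEntry] = []
    for gene in sorted(entries):
        sources, q = entries[gene]
        ev = evidence.get(gene)
        known = classify_gene(gene, ev) or bool(ev and ev.pubmed_support)
        catalog.append(
            CatalogEntry(
                gene=gene,
                status="known" if known else "novel",
                sources=tuple(sources),
                qvalue=q,
            )
        )
    return catalog


def catalog_to_frame(catalog: list[CatalogEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [e.gene for e in catalog],
            "status": [e.status for e in catalog],
            "source": [e.source.value for e in catalog],
            "all_sources": [";".join(s.value for s in e.sources) for e in catalog],
            "qvalue": [e.qvalue if e.qvalue is not None else float("nan") for e in catalog],
        }
    ).set_index("gene")
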