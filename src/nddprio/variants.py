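"""Trio variant classification, functional filtering and per-gene tabulation.

Variants arrive fully annotated (gene symbol, effect class, ReVe score,
population allele frequencies, trio genotypes).  This module decides, per
variant, (a) its inheritance status from the trio genotypes, (b) whether it
qualifies as a protein-truncating variant (PTV) or a deleterious missense
variant (Dmis, ReVe > 0.7), and (c) whether it is rare enough (MAF <= 0.1%
in every population database where it is seen).  Qualifying variants are
tabulated into per-gene, per-class counts that feed the gene-level Bayesian
association model.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


class Effect(str, Enum):
    stop_gain = "stop_gain"
    stop_loss = "stop_loss"
    frameshift = "frameshift"
    splicing = "splicing"
    missense = "missense"
    other = "other"


class Genotype(str, Enum):
    hom_ref = "hom_ref"
    het = "het"
    hom_alt = "hom_alt"
    hemi_alt = "hemi_alt"
    missing = "missing"


class Sex(str, Enum):
    male = "male"
    female = "female"
    unknown = "unknown"


class Inheritance(str, Enum):
    de_novo = "de_novo"
    inherited_paternal = "inherited_paternal"
    inherited_maternal = "inherited_maternal"
    inherited_unphased = "inherited_unphased"
    unknown = "unknown"


class FunctionalClass(str, Enum):
    PTV = "PTV"
    Dmis = "Dmis"
    excluded = "excluded"


#: Effects treated as protein-truncating.
PTV_EFFECTS = frozenset({Effect.stop_gain, Effect.stop_loss, Effect.frameshift, Effect.splicing})

#: Genotypes that carry at least one alternate allele.
CARRIER_GENOTYPES = frozenset({Genotype.het, Genotype.hom_alt, Genotype.hemi_alt})

DEFAULT_REVE_THRESHOLD = 0.7
DEFAULT_MAX_AF = 0.001


class VariantValidationError(ValueError):
    """Raised when an annotated variant violates a structural invariant."""


class NonCarrierProbandError(VariantValidationError):
    """Inheritance is undefined when the proband does not carry the allele."""


def normalize_chrom(chrom: str) -> str:
    """Strip any 'chr' prefix and uppercase X/Y/MT names."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper() if c.lower() in {"x", "y", "mt", "m"} else c


@dataclass(frozen=True)
class AnnotatedVariant:
    """One annotated variant call in one proband.

    Allele frequencies and the ReVe score use ``None`` for missing values.
    Chromosome names are normalized to the prefix-free form on construction.
    """

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: Effect
    reve: float | None = None
    af_gnomad: float | None = None
    af_exac: float | None = None
    af_inhouse: float | None = None
    gt_proband: Genotype = Genotype.missing
    gt_father: Genotype = Genotype.missing
    gt_mother: Genotype = Genotype.missing
    proband_sex: Sex = Sex.unknown
    family_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise VariantValidationError(f"{self.variant_id}: pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise VariantValidationError(f"{self.variant_id}: ref equals alt ({self.ref})")
        if self.reve is not None:
            if not 0.0 <= self.reve <= 1.0:
                raise VariantValidationError(f"{self.variant_id}: ReVe {self.reve} outside [0,1]")
            if self.effect is not Effect.missense:
                raise VariantValidationError(
                    f"{self.variant_id}: ReVe score on non-missense effect {self.effect.value}"
                )
        for name in ("af_gnomad", "af_exac", "af_inhouse"):
            af = getattr(self, name)
            if af is not None and not 0.0 <= af <= 1.0:
                raise VariantValidationError(f"{self.variant_id}: {name}={af} outside [0,1]")
        if self.gt_proband is Genotype.hemi_alt and self.chrom not in {"X", "Y"}:
            raise VariantValidationError(
                f"{self.variant_id}: hemizygous call on autosome {self.chrom}"
            )

    @property
    def allele_frequencies(self) -> tuple[float | None, float | None, float | None]:
        return (self.af_gnomad, self.af_exac, self.af_inhouse)


def classify_inheritance(v: AnnotatedVariant) -> Inheritance:
    """Assign inheritance status from the trio genotypes.

    De novo requires both parents genotyped and homozygous reference; a
    variant is ``unknown`` whenever a required parental genotype is missing
    (singleton probands), matching the cohort's "undetermined" class.
    """
    if v.gt_proband not in CARRIER_GENOTYPES:
        raise NonCarrierProbandError(
            f"{v.variant_id}: non-carrier proband (gt_proband={v.gt_proband.value})"
        )
    if v.gt_father is Genotype.missing or v.gt_mother is Genotype.missing:
        return Inheritance.unknown
    father_carries = v.gt_father in CARRIER_GENOTYPES
    mother_carries = v.gt_mother in CARRIER_GENOTYPES
    if not father_carries and not mother_carries:
        return Inheritance.de_novo
    if father_carries and mother_carries:
        return Inheritance.inherited_unphased
    return Inheritance.inherited_paternal if father_carries else Inheritance.inherited_maternal


def classify_function(
    v: AnnotatedVariant, reve_threshold: float = DEFAULT_REVE_THRESHOLD
) -> FunctionalClass:
    """PTV for truncating effects; Dmis for missense with ReVe strictly above
    the threshold; everything else (including missense at or below it) is
    excluded."""
    if v.effect in PTV_EFFECTS:
        return FunctionalClass.PTV
    if v.effect is Effect.missense:
        if v.reve is None:
            logger.warning("%s: missense without ReVe score, excluded", v.variant_id)
            return FunctionalClass.excluded
        return FunctionalClass.Dmis if v.reve > reve_threshold else FunctionalClass.excluded
    return FunctionalClass.excluded


def passes_frequency_filter(v: AnnotatedVariant, max_af: float = DEFAULT_MAX_AF) -> bool:
    """True iff every observed population allele frequency is <= max_af.

    A variant absent from all databases passes: rare panel variants are
    typically unobserved, and absence of evidence is not treated as common.
    """
    if not 0.0 <= max_af <= 1.0:
        raise VariantValidationError(f"max_af={max_af} outside [0,1]")
    return all(af <= max_af for af in v.allele_frequencies if af is not None)


@dataclass(frozen=True)
class SelectedVariant:
    """A qualifying variant with its functional class and inheritance."""

    variant: AnnotatedVariant
    functional_class: FunctionalClass
    inheritance: Inheritance


def select_potential_functional(
    variants: Iterable[AnnotatedVariant],
    reve_threshold: float = DEFAULT_REVE_THRESHOLD,
    max_af: float = DEFAULT_MAX_AF,
) -> list[SelectedVariant]:
    """Retain PTV/Dmis variants passing the frequency filter, annotated with
    inheritance status.  Rows whose proband does not carry the allele are
    malformed and dropped with a warning."""
    out: list[SelectedVariant] = []
    for v in variants:
        fclass = classify_function(v, reve_threshold)
        if fclass is FunctionalClass.excluded or not passes_frequency_filter(v, max_af):
            continue
        try:
            status = classify_inheritance(v)
        except NonCarrierProbandError as exc:
            logger.warning("dropping malformed row: %s", exc)
            continue
        out.append(SelectedVariant(v, fclass, status))
    return out


def detect_xlinked_hemizygous(selected: Sequence[SelectedVariant]) -> list[SelectedVariant]:
    """Maternally inherited X-linked hemizygous variants in male probands.

    Requires a hemizygous proband call on chrX with a heterozygous mother and
    a non-carrier father.  Hemizygous calls with homozygous-reference parents
    are de novo, not inherited, and are not returned here.  A hemizygous call
    in a proband recorded as female is inconsistent and excluded with a
    warning.
    """
    out: list[SelectedVariant] = []
    for sv in selected:
        v = sv.variant
        if v.chrom != "X" or v.gt_proband is not Genotype.hemi_alt:
            continue
        if v.proband_sex is Sex.female:
            logger.warning(
                "%s: hemizygous chrX call in female proband, excluded as inconsistent",
                v.variant_id,
            )
            continue
        if v.gt_mother is Genotype.het and v.gt_father not in CARRIER_GENOTYPES:
            out.append(sv)
    return out


COUNT_COLUMNS = ("dn_PTV", "dn_Dmis", "case_PTV", "case_Dmis", "ctrl_PTV", "ctrl_Dmis")

#: Inheritance statuses counted in the case (proband burden) arm.
CASE_STATUSES = frozenset(
    {
        Inheritance.inherited_paternal,
        Inheritance.inherited_maternal,
        Inheritance.inherited_unphased,
        Inheritance.unknown,
    }
)


@dataclass
class GeneCountTable:
    """Per-gene qualifying-variant counts with cohort sizes.

    ``counts`` is indexed by gene symbol with integer columns
    dn_PTV, dn_Dmis (de novo over trios), case_PTV, case_Dmis (inherited plus
    undetermined variants over all probands) and ctrl_PTV, ctrl_Dmis
    (control-cohort qualifying variants).
    """

    counts: pd.DataFrame
    n_trios: int
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        for col in COUNT_COLUMNS:
            if col not in self.counts.columns:
                self.counts[col] = 0
        self.counts = self.counts[list(COUNT_COLUMNS)].fillna(0).astype(int).sort_index()
        if (self.counts < 0).any().any():
            raise ValueError("negative qualifying-variant counts")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)


def tabulate_gene_counts(
    selected: Sequence[SelectedVariant],
    n_trios: int,
    n_cases: int,
    n_controls: int,
    control_counts: pd.DataFrame | None = None,
    panel_genes: Iterable[str] | None = None,
) -> GeneCountTable:
    """Tabulate qualifying variants into per-gene per-class counts.

    De novo counts cover trio probands; the case arm pools inherited and
    undetermined variants over all probands (singletons contribute through
    the unknown status).  Control counts come from a separate table
    (gene x {ctrl_PTV, ctrl_Dmis}) since controls are not trio rows.
    """
    tally: Counter[tuple[str, str]] = Counter()
    for sv in selected:
        gene = sv.variant.gene
        if not gene or gene == ".":
            logger.warning("%s: missing gene symbol, skipped", sv.variant.variant_id)
            continue
        cls = sv.functional_class.value
        if sv.inheritance is Inheritance.de_novo:
            tally[(gene, f"dn_{cls}")] += 1
        elif sv.inheritance in CASE_STATUSES:
            tally[(gene, f"case_{cls}")] += 1
    extra_genes = set(panel_genes) if panel_genes is not None else set()
    genes = sorted({g for g, _ in tally} | extra_genes)
    df = pd.DataFrame(0, index=pd.Index(genes, name="gene"), columns=list(COUNT_COLUMNS))
    for (gene, col), n in tally.items():
        df.loc[gene, col] = n
    if control_counts is not None:
        for col in ("ctrl_PTV", "ctrl_Dmis"):
            if col in control_counts.columns:
                common = control_counts.index.intersection(df.index)
                df.loc[common, col] = control_counts.loc[common, col].astype(int)
                extra = control_counts.index.difference(df.index)
                if len(extra):
                    add = pd.DataFrame(0, index=extra, columns=list(COUNT_COLUMNS))
                    add[col] = control_counts.loc[extra, col].astype(int)
                    df = pd.concat([df, add]).groupby(level=0).sum()
    return GeneCountTable(df, n_trios=n_trios, n_cases=n_cases, n_controls=n_controls)


def find_multi_dnv_genes(table: GeneCountTable, min_total_dnv: int = 2) -> pd.DataFrame:
    """Genes with at least ``min_total_dnv`` de novo variants, ordered by
    total de novo count descending then gene symbol ascending."""
    df = table.counts[["dn_PTV", "dn_Dmis"]].copy()
    df["total"] = df["dn_PTV"] + df["dn_Dmis"]
    df = df[df["total"] >= min_total_dnv]
    df = (
        df.assign(_gene=df.index)
        .sort_values(["total", "_gene"], ascending=[False, True])
        .drop(columns="_gene")
    )
    return df
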