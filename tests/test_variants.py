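"""Inheritance/functional classification, filtering and gene tabulation."""

import pandas as pd
import pytest

from nddprio import datasets
from nddprio.variants import (
    Effect,
    FunctionalClass,
    Genotype,
    Inheritance,
    NonCarrierProbandError,
    Sex,
    VariantValidationError,
    classify_function,
    classify_inheritance,
    detect_xlinked_hemizygous,
    find_multi_dnv_genes,
    passes_frequency_filter,
    select_potential_functional,
    tabulate_gene_counts,
)

from conftest import make_variant


@pytest.mark.parametrize(
    "gt_f, gt_m, expected",
    [
        (Genotype.hom_ref, Genotype.hom_ref, Inheritance.de_novo),
        (Genotype.missing, Genotype.hom_ref, Inheritance.unknown),
        (Genotype.hom_ref, Genotype.missing, Inheritance.unknown),
        (Genotype.missing, Genotype.missing, Inheritance.unknown),
        (Genotype.hom_ref, Genotype.het, Inheritance.inherited_maternal),
        (Genotype.het, Genotype.hom_ref, Inheritance.inherited_paternal),
        (Genotype.het, Genotype.het, Inheritance.inherited_unphased),
        (Genotype.hom_alt, Genotype.hom_ref, Inheritance.inherited_paternal),
    ],
)
def test_classify_inheritance(gt_f, gt_m, expected):
    v = make_variant(gt_father=gt_f, gt_mother=gt_m)
    assert classify_inheritance(v) is expected


@pytest.mark.parametrize("gt_p", [Genotype.hom_ref, Genotype.missing])
def test_non_carrier_proband_rejected(gt_p):
    with pytest.raises(NonCarrierProbandError):
        classify_inheritance(make_variant(gt_proband=gt_p))


@pytest.mark.parametrize(
    "effect, reve, expected",
    [
        (Effect.frameshift, None, FunctionalClass.PTV),
        (Effect.stop_gain, None, FunctionalClass.PTV),
        (Effect.stop_loss, None, FunctionalClass.PTV),
        (Effect.splicing, None, FunctionalClass.PTV),
        (Effect.missense, 0.71, FunctionalClass.Dmis),
        (Effect.missense, 0.70, FunctionalClass.excluded),  # boundary is exclusive
        (Effect.missense, 0.5, FunctionalClass.excluded),
        (Effect.missense, None, FunctionalClass.excluded),  # missing score
        (Effect.other, None, FunctionalClass.excluded),
    ],
)
def test_classify_function(effect, reve, expected):
    assert classify_function(make_variant(effect=effect, reve=reve)) is expected


@pytest.mark.parametrize(
    "afs, expected",
    [
        ({"af_gnomad": 0.0005, "af_exac": None, "af_inhouse": 0.0}, True),
        ({"af_gnomad": 0.002}, False),
        ({"af_gnomad": None, "af_exac": None, "af_inhouse": None}, True),  # unobserved passes
        ({"af_gnomad": 0.001}, True),  # boundary inclusive
        ({"af_gnomad": 0.0, "af_exac": 0.01}, False),  # any database can fail it
    ],
)
def test_frequency_filter(afs, expected):
    assert passes_frequency_filter(make_variant(**afs)) is expected


def test_variant_validation_rules():
    with pytest.raises(VariantValidationError):
        make_variant(pos=0)
    with pytest.raises(VariantValidationError):
        make_variant(ref="A", alt="A")
    with pytest.raises(VariantValidationError):
        make_variant(effect=Effect.frameshift, reve=0.9)  # score on non-missense
    with pytest.raises(VariantValidationError):
        make_variant(af_gnomad=1.5)
    with pytest.raises(VariantValidationError):
        make_variant(chrom="7", gt_proband=Genotype.hemi_alt)  # autosomal hemizygous
    # chromosome names are normalized
    assert make_variant(chrom="chrX", gt_proband=Genotype.hemi_alt).chrom == "X"


def test_select_potential_functional_composition():
    variants = [
        make_variant(variant_id="a", effect=Effect.frameshift),
        make_variant(variant_id="b", effect=Effect.missense, reve=0.9),
        make_variant(variant_id="c", effect=Effect.missense, reve=0.5),
        make_variant(variant_id="d", effect=Effect.stop_gain, af_gnomad=0.01),
    ]
    kept = select_potential_functional(variants)
    assert [sv.variant.variant_id for sv in kept] == ["a", "b"]
    assert select_potential_functional([]) == []
    # partition: each retained variant has exactly one class and one status
    for sv in kept:
        assert sv.functional_class in (FunctionalClass.PTV, FunctionalClass.Dmis)
        assert isinstance(sv.inheritance, Inheritance)


def test_detect_xlinked_hemizygous():
    def xv(**kw):
        base = dict(
            chrom="X",
            gt_proband=Genotype.hemi_alt,
            gt_mother=Genotype.het,
            gt_father=Genotype.hom_ref,
            proband_sex=Sex.male,
            effect=Effect.missense,
            reve=0.9,
        )
        base.update(kw)
        return make_variant(**base)

    sel = select_potential_functional(
        [
            xv(variant_id="keep"),
            xv(variant_id="denovo", gt_mother=Genotype.hom_ref),  # de novo, not inherited
            xv(variant_id="female", proband_sex=Sex.female),  # inconsistent call
            make_variant(variant_id="auto"),  # autosomal
        ]
    )
    hemi = detect_xlinked_hemizygous(sel)
    assert [sv.variant.variant_id for sv in hemi] == ["keep"]


def test_tabulate_counts_and_conservation():
    variants = [
        make_variant(variant_id="1", gene="A", family_id="F1"),
        make_variant(variant_id="2", gene="A", family_id="F2"),
        make_variant(variant_id="3", gene="B", effect=Effect.missense, reve=0.9,
                     gt_mother=Genotype.het),
        make_variant(variant_id="4", gene="B", gt_father=Genotype.missing,
                     gt_mother=Genotype.missing),
        make_variant(variant_id="5", gene="", family_id="F3"),  # skipped: no symbol
    ]
    sel = select_potential_functional(variants)
    ctrl = pd.DataFrame({"ctrl_PTV": [3]}, index=pd.Index(["A"], name="gene"))
    t = tabulate_gene_counts(sel, n_trios=10, n_cases=12, n_controls=30, control_counts=ctrl)
    assert t.counts.loc["A", "dn_PTV"] == 2
    assert t.counts.loc["A", "ctrl_PTV"] == 3
    assert t.counts.loc["B", "case_Dmis"] == 1  # inherited maternal
    assert t.counts.loc["B", "case_PTV"] == 1  # undetermined counts in the case arm
    # count conservation: per-class de novo totals match the selected variants
    n_dn = sum(1 for sv in sel if sv.inheritance is Inheritance.de_novo and sv.variant.gene)
    assert t.counts[["dn_PTV", "dn_Dmis"]].to_numpy().sum() == n_dn


def test_tabulate_determinism():
    variants = [make_variant(variant_id=str(i), gene=g) for i, g in enumerate("ABAB")]
    sel = select_potential_functional(variants)
    t1 = tabulate_gene_counts(sel, 5, 5, 5)
    t2 = tabulate_gene_counts(list(reversed(sel)), 5, 5, 5)
    pd.testing.assert_frame_equal(t1.counts, t2.counts)


class TestMultiDnvTable:
    """Checks against the cohort's published recurrent-DNV tabulation."""

    def test_published_tabulation(self):
        counts = datasets.load_multi_dnv_counts()
        multi = find_multi_dnv_genes(counts, min_total_dnv=2)
        assert len(multi) == 21
        assert multi["dn_PTV"].sum() == 28
        assert multi["dn_Dmis"].sum() == 23
        assert (multi["total"] == 3).sum() == 5
        assert (multi["total"] == 2).sum() == 14
        three = set(multi.index[multi["total"] == 3])
        assert three == {"MED13L", "GRIN2B", "KCNQ2", "CTNNB1", "TCF20"}
        # ordering: total descending, then symbol ascending
        totals = multi["total"].to_list()
        assert totals == sorted(totals, reverse=True)
        for t in set(totals):
            grp = multi.index[multi["total"] == t].to_list()
            assert grp == sorted(grp)

    def test_min_total_one_returns_every_dnv_gene(self):
        counts = datasets.load_multi_dnv_counts()
        multi = find_multi_dnv_genes(counts, min_total_dnv=1)
        assert set(multi.index) == set(counts.genes)

    def test_all_zero_counts_empty(self):
        from nddprio.variants import GeneCountTable

        empty = GeneCountTable(
            pd.DataFrame({"dn_PTV": [0], "dn_Dmis": [0]}, index=pd.Index(["X"], name="gene")),
            n_trios=1,
            n_cases=1,
            n_controls=1,
        )
        assert find_multi_dnv_genes(empty).empty
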