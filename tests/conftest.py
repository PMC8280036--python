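import numpy as np
import pandas as pd
import pytest

from nddprio.variants import AnnotatedVariant, Effect, Genotype, Sex


def make_variant(**kwargs) -> AnnotatedVariant:
    """AnnotatedVariant with sensible defaults, overridable per test."""
    defaults = dict(
        variant_id="v1",
        chrom="1",
        pos=1000,
        ref="A",
        alt="T",
        gene="GENE1",
        effect=Effect.frameshift,
        reve=None,
        af_gnomad=0.0,
        af_exac=None,
        af_inhouse=0.0,
        gt_proband=Genotype.het,
        gt_father=Genotype.hom_ref,
        gt_mother=Genotype.hom_ref,
        proband_sex=Sex.male,
        family_id="F1",
    )
    defaults.update(kwargs)
    return AnnotatedVariant(**defaults)


@pytest.fixture
def variant_factory():
    return make_variant


@pytest.fixture
def toy_network_inputs():
    """Hand-enumerated seed-network fixture.

    novel = {n1, n2}, known = {k1, k2, k3}; evidence edges n1-k1, n2-k1,
    n1-n2, n1-k2.  Expected network: nodes {n1, n2, k1} and edges
    {n1-k1, n2-k1, n1-n2} (k2 has only one novel neighbor).
    """
    import networkx as nx

    coexpr = nx.Graph()
    coexpr.add_edge("n1", "k1", r=0.9)
    coexpr.add_edge("n2", "k1", r=0.8)
    ppi = nx.Graph()
    ppi.add_edge("n1", "n2", miscore=0.6)
    ppi.add_edge("n1", "k2", miscore=0.5)
    return {"novel": {"n1", "n2"}, "known": {"k1", "k2", "k3"}, "coexpr": coexpr, "ppi": ppi}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
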