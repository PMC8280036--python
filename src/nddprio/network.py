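"""Seed-gene functional network from PPI and co-expression evidence.

Novel candidate genes act as seeds.  The evidence graph is the union of the
thresholded PPI graph (interaction confidence score >= 0.45) and the
co-expression graph, with edge provenance recorded as ``ppi``, ``coexpr`` or
``both``.  Known candidate genes enter the network only when they touch at
least two novel genes; novel genes are retained only when connected to
another included node.  Network membership is then tested for gene-set
over-representation with a one-sided hypergeometric (Fisher) test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

DEFAULT_MISCORE_THRESHOLD = 0.45
DEFAULT_MIN_NOVEL_CONNECTIONS = 2


def ppi_edges(
    records: Iterable[tuple[str, str, float]],
    threshold: float = DEFAULT_MISCORE_THRESHOLD,
) -> nx.Graph:
    """Thresholded protein-protein interaction graph.

    Keeps edges with score >= threshold (boundary inclusive), collapses
    duplicate pairs keeping the maximum score, and drops self-interactions.
    Malformed records raise a single error carrying a count summary.
    """
    g = nx.Graph()
    bad: list[str] = []
    for lineno, rec in enumerate(records, start=1):
        try:
            a, b, score = rec
            if a is None or b is None:
                raise ValueError
            a, b = str(a), str(b)
            score = float(score)
            if not a or not b or not 0.0 <= score <= 1.0:
                raise ValueError
        except (TypeError, ValueError):
            bad.append(f"line {lineno}: {rec!r}")
            continue
        if a == b:
            continue
        if score < threshold:
            continue
        if g.has_edge(a, b):
            g[a][b]["miscore"] = max(g[a][b]["miscore"], score)
        else:
            g.add_edge(a, b, miscore=score)
    if bad:
        preview = "; ".join(bad[:3])
        raise ValueError(f"{len(bad)} malformed PPI records ({preview})")
    return g


@dataclass
class FunctionalNetwork:
    """Node-labelled (novel/known) graph with per-edge evidence provenance."""

    graph: nx.Graph
    novel: frozenset[str]
    known: frozenset[str]
    isolated_novel: tuple[str, ...]

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)


def build_functional_network(
    novel: set[str],
    known: set[str],
    coexpr: nx.Graph,
    ppi: nx.Graph,
    min_novel_connections: int = DEFAULT_MIN_NOVEL_CONNECTIONS,
    include_known_known: bool = True,
) -> FunctionalNetwork:
    """Assemble the seed-gene network.

    Known genes require >= ``min_novel_connections`` novel neighbors in the
    union evidence graph; novel genes are kept when they have at least one
    evidence edge to an included node (an admitted known gene or another
    novel gene).  Novel genes failing that rule are reported separately as
    isolated seeds.  Known-known edges among included nodes are kept by
    default; set ``include_known_known=False`` to restrict to seed-incident
    edges.
    """
    if novel & known:
        raise ValueError(f"novel and known sets overlap: {sorted(novel & known)[:5]}")
    members = novel | known
    evidence = nx.Graph()
    evidence.add_nodes_from(members)
    for u, v, data in coexpr.edges(data=True):
        if u in members and v in members:
            evidence.add_edge(u, v, provenance="coexpr", r=data.get("r"))
    for u, v, data in ppi.edges(data=True):
        if u in members and v in members:
            if evidence.has_edge(u, v):
                evidence[u][v]["provenance"] = "both"
                evidence[u][v]["miscore"] = data.get("miscore")
            else:
                evidence.add_edge(u, v, provenance="ppi", miscore=data.get("miscore"))

    included_known = {
        g for g in known if sum(nb in novel for nb in evidence.adj[g]) >= min_novel_connections
    }
    anchors = included_known | novel
    included_novel = {g for g in novel if any(nb in anchors for nb in evidence.adj[g])}
    included = included_novel | included_known

    net = nx.Graph()
    for g in sorted(included):
        net.add_node(g, label="novel" if g in novel else "known")
    for u, v, data in evidence.edges(data=True):
        if u in included and v in included:
            if not include_known_known and u in included_known and v in included_known:
                continue
            net.add_edge(u, v, **data)
    isolated = tuple(sorted(novel - included_novel))
    if isolated:
        logger.info("isolated seed genes excluded from network: %s", ", ".join(isolated))
    return FunctionalNetwork(
        graph=net,
        novel=frozenset(novel),
        known=frozenset(known),
        isolated_novel=isolated,
    )


def novel_degree_table(net: FunctionalNetwork) -> pd.DataFrame:
    """Known-candidate neighbor count per seed gene, sorted descending.

    Covers every seed gene; seeds excluded from the network show 0.
    """
    rows = []
    for gene in sorted(net.novel):
        if gene in net.graph:
            deg = sum(net.graph.nodes[nb]["label"] == "known" for nb in net.graph.adj[gene])
        else:
            deg = 0
        rows.append({"gene": gene, "n_known_neighbors": deg})
    df = pd.DataFrame(rows, columns=["gene", "n_known_neighbors"])
    return df.sort_values(
        ["n_known_neighbors", "gene"], ascending=[False, True]
    ).reset_index(drop=True)


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    overlap: int
    odds_ratio: float
    p_value: float
    n_genes: int
    n_annotated: int
    n_background: int


def overrepresentation(
    genes: set[str], annotated_set: set[str], background: set[str], name: str = ""
) -> EnrichmentResult:
    """One-sided hypergeometric over-representation of ``genes`` in
    ``annotated_set`` relative to ``background``.

    p = P(X >= overlap) with X ~ Hypergeom(N=|background|, K=|annotated|,
    n=|genes|).  The odds ratio comes from the 2x2 table with a Haldane 0.5
    correction when any cell is zero.
    """
    if not background:
        raise ValueError("empty background")
    if not genes <= background or not annotated_set <= background:
        raise ValueError("gene sets must be subsets of the background")
    big_n = len(background)
    big_k = len(annotated_set)
    n = len(genes)
    k = len(genes & annotated_set)
    p = float(hypergeom.sf(k - 1, big_n, big_k, n))
    a, b = k, n - k
    c, d = big_k - k, big_n - big_k - (n - k)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return EnrichmentResult(
        name=name,
        overlap=k,
        odds_ratio=float(odds),
        p_value=min(p, 1.0),
        n_genes=n,
        n_annotated=big_k,
        n_background=big_n,
    )
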