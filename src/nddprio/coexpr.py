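"""Brain co-expression graph and the novel-vs-known permutation test.

Expression profiles (genes x samples, emulating postnatal cortical brain
samples) are thresholded on the absolute Pearson correlation (|r| > 0.7) to
give an undirected co-expression graph.  The permutation test asks whether
the novel candidate genes are better connected to the known candidates than
random gene sets of the same size: three statistics are computed on each
null draw — the number of novel genes touching a known gene, the number of
known genes touched, and the number of novel-known edges — and empirical
p-values use the add-one rule p = (b + 1) / (n + 1) so that p is never 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_R_THRESHOLD = 0.7

_POPCOUNT = np.unpackbits(np.arange(256, dtype=np.uint8)[:, None], axis=1).sum(1).astype(np.int64)


class InsufficientSamplesError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample metadata.

    ``metadata`` is indexed by sample with columns ``stage`` (prenatal or
    postnatal), ``region`` and boolean ``cortical``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene symbols: {', '.join(map(str, dup[:5]))}")
        missing = [s for s in self.values.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples without metadata: {', '.join(map(str, missing[:5]))}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def select_samples(m: ExpressionMatrix) -> ExpressionMatrix:
    """Keep postnatal cortical samples only; the gene set is unchanged.
    Idempotent on an already-filtered matrix."""
    meta = m.metadata.loc[m.values.columns]
    keep = meta.index[(meta["stage"] == "postnatal") & meta["cortical"].astype(bool)]
    if len(keep) < 3:
        raise InsufficientSamplesError(
            f"insufficient samples for correlation: {len(keep)} postnatal cortical samples"
        )
    return ExpressionMatrix(m.values[list(keep)], m.metadata.loc[keep])


def coexpression_edges(
    m: ExpressionMatrix, threshold: float = DEFAULT_R_THRESHOLD
) -> nx.Graph:
    """Undirected graph with an edge wherever |Pearson r| strictly exceeds
    the threshold.  All genes appear as nodes; genes with zero variance
    across samples participate in no edges."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold {threshold} outside (0,1)")
    if m.values.shape[1] < 3:
        raise InsufficientSamplesError("need at least 3 samples for correlation")
    g = nx.Graph()
    g.add_nodes_from(m.genes)
    x = m.values.to_numpy(dtype=float)
    sd = x.std(axis=1)
    valid = sd > 0
    n_flat = int((~valid).sum())
    if n_flat:
        logger.info("%d zero-variance genes excluded from correlation", n_flat)
    idx = np.flatnonzero(valid)
    if len(idx) < 2:
        return g
    r = np.corrcoef(x[idx])
    ii, jj = np.nonzero(np.triu(np.abs(r) > threshold, k=1))
    genes = m.values.index.to_numpy()
    for i, j in zip(ii, jj):
        g.add_edge(genes[idx[i]], genes[idx[j]], r=float(r[i, j]))
    return g


@dataclass(frozen=True)
class PermutationResult:
    observed: dict[str, int]
    p_values: dict[str, float]
    n_iterations: int
    seed: int | None
    dropped_genes: tuple[str, ...]


def _connectivity_arrays(
    graph: nx.Graph, pool: list[str], known: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per pool gene: count of known neighbors, and a bit-packed known-gene
    adjacency row (for fast per-draw unions)."""
    known_pos = {g: j for j, g in enumerate(known)}
    adj = np.zeros((len(pool), len(known)), dtype=np.uint8)
    for i, g in enumerate(pool):
        for nb in graph.adj[g]:
            j = known_pos.get(nb)
            if j is not None:
                adj[i, j] = 1
    kcnt = adj.sum(axis=1).astype(np.int64)
    packed = np.packbits(adj, axis=1)
    return kcnt, packed


def _stats(draw_idx: np.ndarray, kcnt: np.ndarray, packed: np.ndarray) -> tuple[int, int, int]:
    sel_k = kcnt[draw_idx]
    novel_connected = int((sel_k > 0).sum())
    connections = int(sel_k.sum())
    union = np.bitwise_or.reduce(packed[draw_idx], axis=0)
    known_connected = int(_POPCOUNT[union].sum())
    return novel_connected, known_connected, connections


def permutation_test(
    graph: nx.Graph,
    novel: set[str],
    known: set[str],
    background: set[str] | None = None,
    n_iter: int = 1_000_000,
    seed: int | None = None,
    chunk_size: int = 4096,
) -> PermutationResult:
    """Connectivity of the novel set to the known set against a resampling null.

    The novel set is redrawn uniformly without replacement from the
    background (all graph genes minus the known set, by default); the known
    set stays fixed.  All three statistics are evaluated on the same null
    draws.  Genes absent from the graph are dropped from the sets first and
    reported in the result.
    """
    if novel & known:
        raise ValueError(f"novel and known sets overlap: {sorted(novel & known)[:5]}")
    graph_genes = set(graph.nodes)
    dropped = tuple(sorted((novel | known) - graph_genes))
    novel_in = sorted(novel & graph_genes)
    known_in = sorted(known & graph_genes)
    if background is None:
        background = graph_genes - known
    pool = sorted((background & graph_genes) - known)
    not_in_pool = set(novel_in) - set(pool)
    if not_in_pool:
        raise ValueError(f"novel genes outside the background: {sorted(not_in_pool)[:5]}")
    k = len(novel_in)
    if len(pool) < k:
        raise ValueError(f"background ({len(pool)}) smaller than novel set ({k})")
    if k == 0:
        raise ValueError("no novel genes present in the co-expression graph")

    kcnt, packed = _connectivity_arrays(graph, pool, known_in)
    pool_pos = {g: i for i, g in enumerate(pool)}
    obs_idx = np.array([pool_pos[g] for g in novel_in])
    obs = _stats(obs_idx, kcnt, packed)

    rng = np.random.default_rng(seed)
    ge = np.zeros(3, dtype=np.int64)
    n_pool = len(pool)
    done = 0
    nbytes = packed.shape[1]
    while done < n_iter:
        m = min(chunk_size, n_iter - done)
        # vectorized sampling without replacement: first k of a random order
        keys = rng.random((m, n_pool))
        draws = np.argpartition(keys, k - 1, axis=1)[:, :k] if k < n_pool else np.tile(
            np.arange(n_pool), (m, 1)
        )
        sel_k = kcnt[draws]  # (m, k)
        a = (sel_k > 0).sum(axis=1)
        c = sel_k.sum(axis=1)
        union = np.bitwise_or.reduce(packed[draws], axis=1)  # (m, nbytes)
        b = _POPCOUNT[union.reshape(m, nbytes)].sum(axis=1)
        ge[0] += int((a >= obs[0]).sum())
        ge[1] += int((b >= obs[1]).sum())
        ge[2] += int((c >= obs[2]).sum())
        done += m

    names = ("novel_connected", "known_connected", "connections")
    p = {name: (int(g) + 1) / (n_iter + 1) for name, g in zip(names, ge)}
    return PermutationResult(
        observed=dict(zip(names, obs)),
        p_values=p,
        n_iterations=n_iter,
        seed=seed,
        dropped_genes=dropped,
    )
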