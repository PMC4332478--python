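"""Consensus modules from an ensemble of clustering runs.

Ensemble runs of the Gibbs sampler (or any third-party clustering) are
summarized by a gene-gene co-occurrence graph whose edge weight is the
fraction of runs in which two genes share a module.  Densely connected sets
of nodes are then extracted iteratively: edges below a weight threshold are
dropped, the dominant (Perron) eigenvector of each connected component's
weighted adjacency ranks its nodes, and the largest eigenvector-ordered
prefix whose mean internal edge weight stays above a density threshold is
emitted as a consensus module.  Genes that never co-cluster reliably remain
unassigned rather than being forced into a module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


@dataclass
class CoOccurrenceGraph:
    """Symmetric gene graph; weight(i,j) = co-clustering frequency in [0,1]."""

    genes: list[str]
    weights: np.ndarray  # (G, G), symmetric, zero diagonal

    def __post_init__(self) -> None:
        g = len(self.genes)
        if self.weights.shape != (g, g):
            raise ValueError("weight matrix shape does not match gene list")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weight matrix must be symmetric")
        if (self.weights < -1e-12).any() or (self.weights > 1 + 1e-12).any():
            raise ValueError("weights must lie in [0, 1]")

    def weight(self, gi: str, gj: str) -> float:
        i = self.genes.index(gi)
        j = self.genes.index(gj)
        return float(self.weights[i, j])


@dataclass
class ConsensusModules:
    """Ordered disjoint consensus gene sets plus the unassigned remainder."""

    modules: list[list[str]]
    unassigned: list[str]

    def module_of(self) -> dict[str, int]:
        return {g: k for k, genes in enumerate(self.modules) for g in genes}


def build_cooccurrence(runs: Sequence[Mapping[str, int]]) -> CoOccurrenceGraph:
    """Pairwise co-clustering frequencies across an ensemble of runs.

    weight(i,j) = (#runs where i and j share a module) / (#runs containing
    both i and j); pairs never observed together get weight 0.
    """
    if not runs:
        raise ValueError("need at least one clustering run")
    genes: list[str] = []
    seen: set[str] = set()
    for run in runs:
        for g in run:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    g_index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    same = np.zeros((n, n))
    both = np.zeros((n, n))
    for run in runs:
        present = np.zeros(n, bool)
        for g in run:
            present[g_index[g]] = True
        k_max = max(run.values()) + 1
        onehot = np.zeros((n, k_max))
        for g, k in run.items():
            onehot[g_index[g], k] = 1.0
        same += onehot @ onehot.T
        both += np.outer(present, present)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(both > 0, same / np.maximum(both, 1), 0.0)
    np.fill_diagonal(w, 0.0)
    return CoOccurrenceGraph(genes, w)


def _perron_vector(w: np.ndarray, tol: float = 1e-9, max_iter: int = 10_000) -> np.ndarray:
    """Dominant eigenvector of a non-negative symmetric matrix.

    Power iteration from the uniform vector; the result is non-negative and
    the deterministic start makes the extraction reproducible.
    """
    n = w.shape[0]
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        nxt = w @ v
        norm = np.linalg.norm(nxt)
        if norm == 0:
            return v
        nxt /= norm
        if np.abs(nxt - v).max() < tol:
            return nxt
        v = nxt
    return v


def _best_prefix(w_sub: np.ndarray, order: np.ndarray, min_density: float) -> int:
    """Largest k such that the first k ordered nodes have mean internal
    edge weight >= min_density; 0 if none with k >= 2."""
    best = 0
    total = 0.0
    for k in range(1, len(order)):
        total += w_sub[order[k], order[:k]].sum()
        pairs = (k + 1) * k / 2
        if total / pairs >= min_density:
            best = k + 1
    return best


def spectral_tight_clusters(
    graph: CoOccurrenceGraph,
    min_weight: float = 0.25,
    min_size: int = 5,
    min_density: float = 0.5,
) -> ConsensusModules:
    """Extract densely connected consensus modules from the weighted graph.

    Iteratively: threshold edges at ``min_weight``, split into connected
    components, rank each component's nodes by the Perron eigenvector of its
    adjacency, keep the largest prefix with mean internal weight >=
    ``min_density``, and emit it if it has at least ``min_size`` genes.
    Extracted genes are removed and the process repeats until nothing more
    can be emitted.
    """
    if not (0 <= min_weight <= 1 and 0 <= min_density <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    w = graph.weights.copy()
    w[w < min_weight] = 0.0
    np.fill_diagonal(w, 0.0)
    remaining = np.arange(len(graph.genes))
    modules: list[list[str]] = []
    while remaining.size >= min_size:
        w_rem = w[np.ix_(remaining, remaining)]
        n_comp, labels = connected_components(csr_matrix(w_rem), directed=False)
        emitted: list[np.ndarray] = []
        # components in order of their smallest node index, for determinism
        comp_order = sorted(range(n_comp), key=lambda c: int(np.argmax(labels == c)))
        for comp in comp_order:
            nodes = np.flatnonzero(labels == comp)
            if nodes.size < min_size:
                continue
            w_comp = w_rem[np.ix_(nodes, nodes)]
            v = _perron_vector(w_comp)
            order = np.argsort(-v, kind="stable")
            k = _best_prefix(w_comp, order, min_density)
            if k >= min_size:
                emitted.append(remaining[nodes[order[:k]]])
        if not emitted:
            break
        for idx in emitted:
            modules.append([graph.genes[i] for i in np.sort(idx)])
        drop = np.concatenate(emitted)
        remaining = remaining[~np.isin(remaining, drop)]
    assigned = {g for mod in modules for g in mod}
    unassigned = [g for g in graph.genes if g not in assigned]
    return ConsensusModules(modules, unassigned)
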