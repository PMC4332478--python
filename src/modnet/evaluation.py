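"""Post-processing: gene-set enrichment per module and network benchmarking.

Module enrichment is a plain hypergeometric over-representation test
(upper tail) against a flat gene -> terms annotation, Benjamini-Hochberg
corrected across terms within each module.  Network benchmarking computes
the relative enrichment of inferred regulator-target pairs at short
distances in a reference interaction network, compared to the same pairs
with endpoints randomly re-assigned.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def module_enrichment(
    modules: Mapping[int, Sequence[str]] | Sequence[Sequence[str]],
    annotation: Mapping[str, Iterable[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of every annotated term in every module.

    For a module of n genes drawn from a universe of M genes of which K are
    annotated with a term, the p-value of observing k annotated module genes
    is P(X >= k) for X ~ Hypergeom(M, K, n).  BH correction is applied
    across terms within each module.  Module genes must be a subset of the
    universe; terms with no annotated universe gene are skipped.
    """
    if isinstance(modules, Mapping):
        module_items = sorted(modules.items())
    else:
        module_items = list(enumerate(modules))
    uni = set(universe)
    m_total = len(uni)
    term_genes: dict[str, set[str]] = {}
    for g, terms in annotation.items():
        if g not in uni:
            continue
        for t in terms:
            term_genes.setdefault(t, set()).add(g)
    skipped = set()
    for g, terms in annotation.items():
        for t in terms:
            if t not in term_genes:
                skipped.add(t)
    for t in sorted(skipped):
        logger.warning("term %r has no annotated gene in the universe; skipped", t)
    rows = []
    for mod_id, genes in module_items:
        gene_set = set(genes)
        if not gene_set <= uni:
            raise ValueError(f"module {mod_id} contains genes outside the universe")
        n = len(gene_set)
        pvals, keys = [], []
        for term in sorted(term_genes):
            hit = term_genes[term]
            k = len(gene_set & hit)
            p = float(hypergeom.sf(k - 1, m_total, len(hit), n))
            pvals.append(min(p, 1.0))
            keys.append((term, k, len(hit)))
        if not pvals:
            continue
        _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
        for (term, k, big_k), p, q in zip(keys, pvals, p_adj):
            rows.append(
                {
                    "module": mod_id,
                    "term": term,
                    "overlap": k,
                    "term_size": big_k,
                    "module_size": n,
                    "universe_size": m_total,
                    "p_value": p,
                    "p_adjusted": q,
                }
            )
    return pd.DataFrame(rows)


def expand_regulator_network(
    selected: Mapping[tuple[str, int], float],
    modules: Mapping[int, Sequence[str]] | Sequence[Sequence[str]],
    mode: str = "all_genes",
) -> list[tuple[str, str]]:
    """Expand selected (regulator, module) pairs to regulator-gene edges.

    ``all_genes`` links the regulator to every gene of the module;
    ``representative`` links it only to the module's lexicographically first
    gene (a minimal one-edge-per-module summary).
    """
    if isinstance(modules, Mapping):
        mod_map = {int(k): list(v) for k, v in modules.items()}
    else:
        mod_map = {k: list(v) for k, v in enumerate(modules)}
    edges = []
    for (reg, mod), _ in sorted(selected.items()):
        genes = mod_map.get(mod, [])
        if mode == "representative":
            genes = sorted(genes)[:1]
        elif mode != "all_genes":
            raise ValueError(f"unknown expansion mode {mode!r}")
        for g in genes:
            if g != reg:
                edges.append((reg, g))
    return edges


def _pair_fractions(
    pairs: set[frozenset],
    dist_cache: dict[str, dict[str, int]],
    graph: nx.Graph,
    max_distance: int,
) -> np.ndarray:
    """fraction of pairs with shortest-path distance <= d, for d = 1..D."""
    counts = np.zeros(max_distance)
    for pair in pairs:
        a, b = tuple(pair)
        if a not in dist_cache:
            dist_cache[a] = nx.single_source_shortest_path_length(
                graph, a, cutoff=max_distance
            )
        d = dist_cache[a].get(b)
        if d is not None and 1 <= d <= max_distance:
            counts[d - 1 :] += 1
    return counts / max(len(pairs), 1)


def ppi_relative_enrichment(
    inferred_edges: Sequence[tuple[str, str]],
    reference_network: nx.Graph | Sequence[tuple[str, str]],
    max_distance: int = 4,
    num_rand: int = 100,
    seed: int = 0,
    degree_preserving: bool = False,
) -> pd.DataFrame:
    """Relative enrichment of inferred pairs at short reference distances.

    f(d) is the fraction of inferred pairs whose unweighted undirected
    shortest-path distance in the reference network is <= d; f_rand(d) is its
    mean over ``num_rand`` randomizations in which each inferred edge's
    endpoints are re-assigned uniformly to network genes (or, with
    ``degree_preserving``, the reference network itself is rewired).  The
    enrichment at d is f(d) / f_rand(d).  Inferred pairs with an endpoint
    absent from the reference are dropped (and counted in the ``n_dropped``
    attribute of the returned frame).
    """
    if isinstance(reference_network, nx.Graph):
        graph = reference_network
    else:
        graph = nx.Graph()
        graph.add_edges_from(reference_network)
    if graph.number_of_edges() == 0:
        raise ValueError("reference network has no edges")
    nodes = sorted(graph.nodes)
    pairs = set()
    dropped = 0
    for a, b in inferred_edges:
        if a == b:
            continue
        if a in graph and b in graph:
            pairs.add(frozenset((a, b)))
        else:
            dropped += 1
    if not pairs:
        raise ValueError("no inferred pair maps onto the reference network")
    dist_cache: dict[str, dict[str, int]] = {}
    f_obs = _pair_fractions(pairs, dist_cache, graph, max_distance)
    rng = np.random.default_rng(seed)
    rand_f = np.empty((num_rand, max_distance))
    n_edges = len(pairs)
    for r in range(num_rand):
        if degree_preserving:
            rand_graph = nx.double_edge_swap(
                graph.copy(),
                nswap=2 * graph.number_of_edges(),
                max_tries=100 * graph.number_of_edges(),
                seed=int(rng.integers(2**31 - 1)),
            )
            cache_r: dict[str, dict[str, int]] = {}
            rand_f[r] = _pair_fractions(pairs, cache_r, rand_graph, max_distance)
            continue
        rand_pairs = set()
        while len(rand_pairs) < n_edges:
            a, b = rng.choice(len(nodes), size=2, replace=False)
            rand_pairs.add(frozenset((nodes[int(a)], nodes[int(b)])))
        rand_f[r] = _pair_fractions(rand_pairs, dist_cache, graph, max_distance)
    f_rand = rand_f.mean(axis=0)
    f_rand_se = rand_f.std(axis=0, ddof=1) / np.sqrt(num_rand)
    with np.errstate(divide="ignore", invalid="ignore"):
        enrichment = np.where(f_rand > 0, f_obs / f_rand, np.nan)
    out = pd.DataFrame(
        {
            "distance": np.arange(1, max_distance + 1),
            "f_observed": f_obs,
            "f_random": f_rand,
            "f_random_se": f_rand_se,
            "enrichment": enrichment,
        }
    )
    out.attrs["n_pairs"] = len(pairs)
    out.attrs["n_dropped"] = dropped
    return out
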