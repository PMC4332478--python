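"""Per-module condition clustering and hierarchical condition trees.

For a fixed set of consensus modules, the samples are re-clustered within
each module with the same Gibbs machinery used for two-way clustering (the
gene partition is frozen).  The resulting flat partition is then assembled
into a binary tree by agglomerating, at each step, the pair of clusters
whose merge has the largest Bayesian score change, so the whole pipeline
stays under one scoring model.  Internal nodes record the merge score;
regulator assignment later attaches candidate regulators to these nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gibbs import GibbsState
from .io import ConditionTree, ExpressionMatrix, TreeNode
from .score import BlockSummary, NormalGammaPrior, block_log_marginal


@dataclass
class ConditionTreeConfig:
    num_sweeps: int = 50
    burn_in: int = 10
    temperature: float = 1.0
    greedy_sweeps: int = 10
    seed: int = 0


def cluster_conditions(
    matrix: ExpressionMatrix,
    module_genes: list[str],
    prior: NormalGammaPrior | None = None,
    config: ConditionTreeConfig | None = None,
) -> dict[str, int]:
    """Partition the samples for one module by Gibbs sampling.

    Returns the best-scoring sample partition visited (sample id -> cluster
    index, densely indexed).  Deterministic under the config seed.
    """
    if not module_genes:
        raise ValueError("module_genes must be non-empty")
    prior = prior or NormalGammaPrior()
    config = config or ConditionTreeConfig()
    gi = [matrix.gene_index(g) for g in module_genes]
    sub = ExpressionMatrix(list(module_genes), list(matrix.sample_ids), matrix.values[gi])
    rng = np.random.default_rng(config.seed)
    state = GibbsState(sub, prior, rng, init_modules=1)
    best_score = -np.inf
    best_labels = state.modules[0].labels.copy()
    for sweep in range(config.num_sweeps):
        state.sweep_conditions(rng, config.temperature)
        if sweep >= config.burn_in and state.running_total > best_score:
            best_score = state.running_total
            best_labels = state.modules[0].labels.copy()
    for _ in range(config.greedy_sweeps):
        moved = state.sweep_conditions(rng, greedy=True)
        if state.running_total > best_score:
            best_score = state.running_total
            best_labels = state.modules[0].labels.copy()
        if moved == 0:
            break
    # dense relabeling in first-appearance order
    remap: dict[int, int] = {}
    part: dict[str, int] = {}
    for s, lab in zip(matrix.sample_ids, best_labels):
        lab = int(lab)
        if lab not in remap:
            remap[lab] = len(remap)
        part[s] = remap[lab]
    return part


def build_tree(
    partition: dict[str, int],
    module_genes: list[str],
    matrix: ExpressionMatrix,
    prior: NormalGammaPrior | None = None,
    module: int = 0,
) -> ConditionTree:
    """Assemble a flat sample partition into a binary condition tree.

    Clusters are merged bottom-up; each step joins the pair with the largest
    (least negative) Bayesian score change, recorded as the internal node's
    merge score.  The left child is the one with lower mean module
    expression, a fixed orientation convention consumed by regulator split
    signs.  With L leaves the tree has exactly L-1 internal nodes.
    """
    prior = prior or NormalGammaPrior()
    gi = [matrix.gene_index(g) for g in module_genes]
    clusters: dict[int, list[str]] = {}
    for s, c in partition.items():
        clusters.setdefault(c, []).append(s)

    def block(samples: list[str]) -> BlockSummary:
        cols = [matrix.sample_index(s) for s in samples]
        return BlockSummary.from_values(matrix.values[np.ix_(gi, cols)])

    def mean_expr(samples: list[str]) -> float:
        cols = [matrix.sample_index(s) for s in samples]
        vals = matrix.values[np.ix_(gi, cols)]
        return float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else 0.0

    nodes: list[TreeNode] = []
    summaries: list[BlockSummary] = []
    scores: list[float] = []
    for c in sorted(clusters):
        nodes.append(TreeNode(samples=sorted(clusters[c])))
        summaries.append(block(clusters[c]))
        scores.append(block_log_marginal(summaries[-1], prior))

    while len(nodes) > 1:
        best: tuple[float, int, int] | None = None
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                merged = summaries[i].merge(summaries[j])
                delta = block_log_marginal(merged, prior) - scores[i] - scores[j]
                if best is None or delta > best[0]:
                    best = (delta, i, j)
        delta, i, j = best  # type: ignore[misc]
        a, b = nodes[i], nodes[j]
        if mean_expr(a.all_samples()) <= mean_expr(b.all_samples()):
            left, right = a, b
        else:
            left, right = b, a
        merged_summary = summaries[i].merge(summaries[j])
        parent = TreeNode(left=left, right=right, merge_score=delta)
        for idx in sorted((i, j), reverse=True):
            del nodes[idx], summaries[idx], scores[idx]
        nodes.append(parent)
        summaries.append(merged_summary)
        scores.append(block_log_marginal(merged_summary, prior))

    return ConditionTree(module, nodes[0])


def build_module_trees(
    matrix: ExpressionMatrix,
    modules: dict[str, int] | list[list[str]],
    prior: NormalGammaPrior | None = None,
    config: ConditionTreeConfig | None = None,
) -> dict[int, ConditionTree]:
    """Cluster conditions and build one condition tree per module."""
    prior = prior or NormalGammaPrior()
    config = config or ConditionTreeConfig()
    if isinstance(modules, dict):
        by_k: dict[int, list[str]] = {}
        for g, k in modules.items():
            by_k.setdefault(k, []).append(g)
        module_lists = [by_k[k] for k in sorted(by_k)]
    else:
        module_lists = list(modules)
    trees: dict[int, ConditionTree] = {}
    for k, genes in enumerate(module_lists):
        cfg = ConditionTreeConfig(
            num_sweeps=config.num_sweeps,
            burn_in=config.burn_in,
            temperature=config.temperature,
            greedy_sweeps=config.greedy_sweeps,
            seed=config.seed * 100_003 + k,
        )
        part = cluster_conditions(matrix, genes, prior, cfg)
        trees[k] = build_tree(part, genes, matrix, prior, module=k)
    return trees
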