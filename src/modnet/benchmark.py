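"""Planted-truth recovery benchmarks on the synthetic generator.

These drive the package's own end-to-end checks: an ensemble of Gibbs runs
plus consensus clustering must recover the planted modules, and the
regulator pipeline must rank each module's planted regulator first and well
above an empirical null.  The same entry points back the reproduction
script, so reported numbers are always recomputed from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consensus import ConsensusModules, build_cooccurrence, spectral_tight_clusters
from .gibbs import GibbsConfig, run_gibbs
from .regulators import assign_regulators, build_null, consensus_score
from .synthetic import SyntheticParams, generate
from .trees import ConditionTreeConfig, build_module_trees


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions (1 = identical)."""
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(labels_a, labels_b))


def consensus_labels(gene_ids, consensus: ConsensusModules) -> list[int]:
    """Module labels for ARI; unassigned genes become singleton clusters so
    non-assignment is penalized rather than ignored."""
    module_of = consensus.module_of()
    labels = []
    next_singleton = len(consensus.modules)
    for g in gene_ids:
        if g in module_of:
            labels.append(module_of[g])
        else:
            labels.append(next_singleton)
            next_singleton += 1
    return labels


@dataclass
class ModuleRecoveryResult:
    ari: float
    n_modules: int
    n_assigned: int
    run_aris: list[float] = field(default_factory=list)


def module_recovery(
    master_seed: int,
    n_runs: int = 10,
    params: SyntheticParams | None = None,
    num_sweeps: int = 100,
    burn_in: int = 20,
) -> ModuleRecoveryResult:
    """Generate a benchmark instance, run an ensemble of seeded Gibbs
    clusterings, build consensus modules and score them against the truth."""
    params = params or SyntheticParams()
    matrix, _, truth = generate(params, seed=master_seed)
    truth_labels = [truth.module_of[g] for g in matrix.gene_ids]
    runs = []
    run_aris = []
    for r in range(n_runs):
        config = GibbsConfig(
            num_sweeps=num_sweeps, burn_in=burn_in, seed=master_seed * 1000 + r
        )
        clustering = run_gibbs(matrix, config=config).clustering
        runs.append(clustering.module_of)
        run_aris.append(
            adjusted_rand_index(
                truth_labels, [clustering.module_of[g] for g in matrix.gene_ids]
            )
        )
    graph = build_cooccurrence(runs)
    consensus = spectral_tight_clusters(graph)
    ari = adjusted_rand_index(truth_labels, consensus_labels(matrix.gene_ids, consensus))
    return ModuleRecoveryResult(
        ari=ari,
        n_modules=len(consensus.modules),
        n_assigned=sum(len(m) for m in consensus.modules),
        run_aris=run_aris,
    )


@dataclass
class RegulatorRecoveryResult:
    top1: list[bool]                 # per module: planted regulator ranked #1
    above_null_q99: list[bool]       # per module: planted score > null q99
    planted_scores: list[float]
    null_q99: float


def regulator_recovery(
    seed: int,
    n_tree_seeds: int = 5,
    n_null_draws: int = 100,
    params: SyntheticParams | None = None,
) -> RegulatorRecoveryResult:
    """Score candidate regulators against condition-tree ensembles built on
    the planted modules and compare the planted regulator to the rest and to
    the random-regulator null."""
    params = params or SyntheticParams()
    matrix, regs, truth = generate(params, seed=seed)
    trees: dict[int, list] = {}
    for t_seed in range(n_tree_seeds):
        built = build_module_trees(
            matrix,
            truth.module_of,
            config=ConditionTreeConfig(seed=seed * 100 + t_seed),
        )
        for k, tree in built.items():
            trees.setdefault(k, []).append(tree)
    assignments = assign_regulators(trees, regs)
    scores = consensus_score(assignments)
    null = build_null(regs, trees, n_draws=n_null_draws, seed=seed)
    q99 = float(np.quantile(null.draws, 0.99))
    top1, above, planted_scores = [], [], []
    for m in sorted(trees):
        ranked = sorted(
            ((r, s) for (r, mm), s in scores.items() if mm == m),
            key=lambda t: -t[1],
        )
        planted = truth.planted_regulator[m]
        planted_score = dict(ranked)[planted]
        top1.append(ranked[0][0] == planted)
        above.append(planted_score > q99)
        planted_scores.append(planted_score)
    return RegulatorRecoveryResult(top1, above, planted_scores, q99)
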