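"""Probabilistic assignment of candidate regulators to condition-tree splits.

Each internal node of a condition tree separates a low-expression from a
high-expression set of samples.  A candidate regulator explains the split if
a threshold z on its (standardized) profile separates the two sides; the fit
is scored by a soft logistic split log-likelihood

    LL(r, z, o) = sum_{c in high} ln sigma(o * beta * (x_c - z))
                + sum_{c in low}  ln sigma(-o * beta * (x_c - z)),

maximized over z (midpoints of consecutive sorted regulator values) and
orientation o = +-1.  Per node, regulator posteriors are the softmax of the
maximized log-likelihoods over all candidates.  Posteriors are aggregated
over a tree ensemble into a consensus score per (regulator, module),

    s(r, m) = sum_trees sum_nodes p(r | node) * 2^(-level),

so a regulator supported by many trees near the root scores highest.  An
empirical null of scores of randomly permuted regulators calibrates
significance; top-fraction selection and hub ranking prioritize recurrently
selected (e.g. copy-number) driver candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import log_expit, logsumexp

from .io import ConditionTree, RegulatorMatrix


@dataclass
class SplitFit:
    split_value: float
    orientation: int
    loglik: float


@dataclass
class RegulatorAssignment:
    regulator_id: str
    module: int
    node_id: str
    split_value: float
    orientation: int
    posterior: float
    level: int


@dataclass
class RegulatorScore:
    regulator_id: str
    module: int
    score: float
    null_quantile: float = math.nan


@dataclass
class RegulatorNull:
    """Empirical distribution of consensus scores of random regulators."""

    draws: np.ndarray
    size: int
    seed: int

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.draws, q))

    def quantile_of(self, score: float) -> float:
        """Fraction of null draws strictly below ``score``."""
        return float(np.mean(self.draws < score))


def score_split(
    reg_values: Mapping[str, float],
    left_samples: Sequence[str],
    right_samples: Sequence[str],
    beta: float = 5.0,
) -> SplitFit:
    """Best soft split of a regulator profile against a left/right partition.

    Orientation +1 means the right (high-expression) side has high regulator
    values.  Samples missing from ``reg_values`` (or NaN) are skipped.  A
    constant regulator yields the flat split at its value (valid, low LL).
    Ties are broken toward orientation +1 and the smallest threshold.
    """
    if set(left_samples) & set(right_samples):
        raise ValueError("left and right sample sets must be disjoint")
    if not left_samples or not right_samples:
        raise ValueError("both sides of the split must be non-empty")
    x, side = [], []
    for s in left_samples:
        v = reg_values.get(s, math.nan)
        if not math.isnan(v):
            x.append(v)
            side.append(-1.0)
    for s in right_samples:
        v = reg_values.get(s, math.nan)
        if not math.isnan(v):
            x.append(v)
            side.append(1.0)
    if not x:
        return SplitFit(math.nan, 1, -math.inf)
    x = np.asarray(x)
    side = np.asarray(side)
    uniq = np.unique(x)
    if uniq.size < 2:
        zs = np.array([uniq[0]])
    else:
        zs = 0.5 * (uniq[:-1] + uniq[1:])
    # ll[o, z] = sum_i log sigma(o * side_i * beta * (x_i - z))
    t = beta * (x[None, :] - zs[:, None])  # (Z, n)
    ll_plus = log_expit(side[None, :] * t).sum(axis=1)
    ll_minus = log_expit(-side[None, :] * t).sum(axis=1)
    i_plus = int(np.argmax(ll_plus))
    i_minus = int(np.argmax(ll_minus))
    if ll_plus[i_plus] >= ll_minus[i_minus]:
        return SplitFit(float(zs[i_plus]), 1, float(ll_plus[i_plus]))
    return SplitFit(float(zs[i_minus]), -1, float(ll_minus[i_minus]))


def _standardize(reg_matrix: RegulatorMatrix) -> RegulatorMatrix:
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(reg_matrix.values, axis=1, keepdims=True)
        sd = np.nanstd(reg_matrix.values, axis=1, keepdims=True)
    sd[~np.isfinite(sd) | (sd == 0)] = 1.0
    mu[~np.isfinite(mu)] = 0.0
    return RegulatorMatrix(
        list(reg_matrix.regulator_ids),
        list(reg_matrix.sample_ids),
        (reg_matrix.values - mu) / sd,
        "continuous",
    )


@dataclass
class _NodeRecord:
    module: int
    tree_index: int
    node_id: str
    level: int
    left: list[str]
    right: list[str]
    fits: list[SplitFit] | None = None  # per candidate regulator

    @property
    def lls(self) -> np.ndarray:
        return np.array([f.loglik for f in self.fits])


def _collect_nodes(trees: Mapping[int, Sequence[ConditionTree]]) -> list[_NodeRecord]:
    records = []
    for module in sorted(trees):
        for t_idx, tree in enumerate(trees[module]):
            for n_idx, node in enumerate(tree.root.internal_nodes()):
                records.append(
                    _NodeRecord(
                        module=module,
                        tree_index=t_idx,
                        node_id=f"m{module}.t{t_idx}.n{n_idx}",
                        level=node.level,
                        left=node.left.all_samples(),
                        right=node.right.all_samples(),
                    )
                )
    return records


def _fit_nodes(
    records: list[_NodeRecord], reg_matrix: RegulatorMatrix, beta: float
) -> None:
    values = {
        r: dict(zip(reg_matrix.sample_ids, reg_matrix.values[i]))
        for i, r in enumerate(reg_matrix.regulator_ids)
    }
    for rec in records:
        rec.fits = [
            score_split(values[r], rec.left, rec.right, beta)
            for r in reg_matrix.regulator_ids
        ]


def assign_node_regulators(
    record: _NodeRecord, regulator_ids: Sequence[str]
) -> list[RegulatorAssignment]:
    """Softmax posteriors over candidate regulators at one internal node."""
    lls = record.lls
    post = np.exp(lls - logsumexp(lls))
    return [
        RegulatorAssignment(
            regulator_id=r,
            module=record.module,
            node_id=record.node_id,
            split_value=record.fits[i].split_value,
            orientation=record.fits[i].orientation,
            posterior=float(post[i]),
            level=record.level,
        )
        for i, r in enumerate(regulator_ids)
    ]


def assign_regulators(
    trees: Mapping[int, Sequence[ConditionTree]],
    reg_matrix: RegulatorMatrix,
    beta: float = 5.0,
    standardize: bool = True,
    attach: bool = False,
) -> list[RegulatorAssignment]:
    """Score every candidate regulator at every internal node of the ensemble.

    With ``attach=True`` the maximum-posterior regulator of each node is also
    recorded on the tree node itself (for XML export).
    """
    if standardize and reg_matrix.kind == "continuous":
        reg_matrix = _standardize(reg_matrix)
    records = _collect_nodes(trees)
    _fit_nodes(records, reg_matrix, beta)
    out: list[RegulatorAssignment] = []
    for rec in records:
        assignments = assign_node_regulators(rec, reg_matrix.regulator_ids)
        out.extend(assignments)
        if attach:
            best = max(assignments, key=lambda a: a.posterior)
            node = trees[rec.module][rec.tree_index].root.internal_nodes()[
                int(rec.node_id.rsplit("n", 1)[1])
            ]
            node.regulators = [best]
    return out


def consensus_score(
    assignments: Sequence[RegulatorAssignment],
    level_base: float = 2.0,
) -> dict[tuple[str, int], float]:
    """Aggregate node posteriors into s(r, m) = sum p * base^(-level).

    The sum runs over every internal node of every tree of module m, so a
    regulator assigned in more trees, with higher posterior, closer to the
    root, scores higher.  Root nodes (level 0) weigh ``level_base`` times
    level-1 nodes.
    """
    scores: dict[tuple[str, int], float] = {}
    for a in assignments:
        key = (a.regulator_id, a.module)
        scores[key] = scores.get(key, 0.0) + a.posterior * level_base ** (-a.level)
    return scores


def build_null(
    reg_matrix: RegulatorMatrix,
    trees: Mapping[int, Sequence[ConditionTree]],
    n_draws: int = 100,
    seed: int = 0,
    beta: float = 5.0,
    standardize: bool = True,
    level_base: float = 2.0,
) -> RegulatorNull:
    """Empirical null of consensus scores for randomly assigned regulators.

    Each draw permutes the sample labels of a uniformly chosen real regulator
    (preserving its marginal distribution, destroying sample linkage), scores
    it at every internal node of one uniformly chosen module's trees in
    competition with the real candidates, and records its consensus score.
    """
    if n_draws < 1:
        raise ValueError("need at least one null draw")
    if standardize and reg_matrix.kind == "continuous":
        reg_matrix = _standardize(reg_matrix)
    records = _collect_nodes(trees)
    _fit_nodes(records, reg_matrix, beta)
    by_module: dict[int, list[_NodeRecord]] = {}
    for rec in records:
        by_module.setdefault(rec.module, []).append(rec)
    modules = sorted(by_module)
    rng = np.random.default_rng(seed)
    samples = reg_matrix.sample_ids
    draws = np.empty(n_draws)
    for d in range(n_draws):
        r_idx = int(rng.integers(reg_matrix.n_regulators))
        perm = rng.permutation(len(samples))
        fake = dict(zip(samples, reg_matrix.values[r_idx][perm]))
        module = modules[int(rng.integers(len(modules)))]
        s = 0.0
        for rec in by_module[module]:
            fit = score_split(fake, rec.left, rec.right, beta)
            lls = rec.lls
            p = math.exp(fit.loglik - logsumexp(np.append(lls, fit.loglik)))
            s += p * level_base ** (-rec.level)
        draws[d] = s
    return RegulatorNull(draws=draws, size=n_draws, seed=seed)


def scores_with_null(
    scores: Mapping[tuple[str, int], float], null: RegulatorNull
) -> list[RegulatorScore]:
    return [
        RegulatorScore(r, m, s, null.quantile_of(s))
        for (r, m), s in sorted(scores.items(), key=lambda kv: -kv[1])
    ]


def select_top_fraction(
    scores: Mapping[tuple[str, int], float], fraction: float = 0.01
) -> tuple[dict[tuple[str, int], float], list[str]]:
    """Keep the ceil(fraction * #pairs) highest-scoring (regulator, module)
    pairs; ties at the cut are kept.  Returns the kept pairs and the distinct
    regulators they contain."""
    if not scores:
        raise ValueError("empty score list")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    k = math.ceil(fraction * len(items))
    cut = items[k - 1][1]
    kept = {pair: s for pair, s in items if s >= cut}
    regs: list[str] = []
    for (r, _), _ in sorted(kept.items(), key=lambda kv: (-kv[1], kv[0])):
        if r not in regs:
            regs.append(r)
    return kept, regs


def hub_scores(
    selected: Mapping[tuple[str, int], float]
) -> list[tuple[str, int, float]]:
    """Rank regulators by the sum of their per-module scores.

    Returns (regulator, number of modules, sum of scores), sorted by sum
    descending, ties by module count then id.
    """
    if not selected:
        raise ValueError("empty selection")
    agg: dict[str, tuple[int, float]] = {}
    for (r, _), s in selected.items():
        n, tot = agg.get(r, (0, 0.0))
        agg[r] = (n + 1, tot + s)
    return sorted(
        ((r, n, tot) for r, (n, tot) in agg.items()),
        key=lambda t: (-t[2], -t[1], t[0]),
    )
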