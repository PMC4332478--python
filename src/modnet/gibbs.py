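"""Two-way Gibbs sampler for co-expression modules and condition clusters.

One run alternates (i) a gene sweep, in which every gene is removed from its
module and reassigned among all existing modules plus one fresh empty module
with probability proportional to exp(delta_score / T), and (ii) a condition
sweep, in which every sample is reassigned among each module's condition
clusters plus one fresh empty cluster.  The number of modules and of
condition clusters is therefore open-ended and adapts to the data.  With
T -> 0 the sampler becomes a greedy hill climber that only accepts moves with
a non-negative score change.

A run is fully determined by (matrix, prior, config): the seed fixes the
whole trajectory.  An ensemble of runs with different seeds is the input of
the consensus-module step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, TwoWayClustering
from .score import NormalGammaPrior, ScoreTable, total_score


@dataclass
class GibbsConfig:
    """Run-length, temperature and seeding controls for one sampler run.

    ``num_sweeps`` sampled sweeps are followed by ``greedy_sweeps`` greedy
    ones; the best-scoring state visited after ``burn_in`` sweeps is returned.
    """

    init_modules: int = 10
    num_sweeps: int = 100
    burn_in: int = 20
    temperature: float = 1.0
    anneal_factor: float = 1.0
    greedy_sweeps: int = 10
    seed: int = 0
    sample_condition_clusters: bool = True

    def __post_init__(self) -> None:
        if self.init_modules < 1:
            raise ValueError("init_modules must be >= 1")
        if self.num_sweeps < 1:
            raise ValueError("num_sweeps must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass
class GibbsResult:
    clustering: TwoWayClustering
    score: float
    sweep_scores: list[float]
    move_scores: list[float]
    n_modules: int = 0
    greedy_move_start: int = 0  # index into move_scores where greedy phase begins


class _Module:
    __slots__ = ("labels", "n", "s", "ss", "bs", "cache", "n_genes", "rn", "rs", "rss")

    def __init__(self, labels, n, s, ss, bs, n_genes):
        self.labels = labels  # (S,) condition-cluster label per sample
        self.n = n  # per-cluster non-missing counts
        self.s = s  # per-cluster sums
        self.ss = ss  # per-cluster sums of squares
        self.bs = bs  # per-cluster block scores
        self.cache = float(bs.sum())
        self.n_genes = n_genes
        self.rn = self.rs = self.rss = None  # per-gene per-cluster row stats


class GibbsState:
    """Mutable sampler state with incrementally maintained block statistics."""

    def __init__(
        self,
        matrix: ExpressionMatrix,
        prior: NormalGammaPrior,
        rng: np.random.Generator,
        init_modules: int = 10,
    ):
        self.matrix = matrix
        self.prior = prior
        X = matrix.values
        self.mask = (~np.isnan(X)).astype(float)
        if (self.mask.sum(axis=1) == 0).any():
            bad = matrix.gene_ids[int(np.argmin(self.mask.sum(axis=1)))]
            raise ValueError(f"gene {bad!r} has no observed values")
        self.X0 = np.where(np.isnan(X), 0.0, X)
        self.X2 = self.X0 * self.X0
        self.G, self.S = X.shape
        # whole-row statistics, used for fresh single-cluster modules
        self.tn = self.mask.sum(axis=1)
        self.ts = self.X0.sum(axis=1)
        self.tss = self.X2.sum(axis=1)
        self.table = ScoreTable(prior, int(self.tn.sum()))
        k0 = min(init_modules, self.G)
        self.module_of = rng.integers(0, k0, size=self.G)
        self.modules: list[_Module] = []
        for k in range(k0):
            genes = np.flatnonzero(self.module_of == k)
            self.modules.append(self._fresh_module(genes))
        self.module_of = np.asarray(self.module_of, dtype=np.int64)
        self.running_total = sum(m.cache for m in self.modules)
        self.move_scores: list[float] = []

    # -- construction helpers ------------------------------------------------

    def _fresh_module(self, genes: np.ndarray) -> _Module:
        labels = np.zeros(self.S, dtype=np.int64)
        n = np.array([self.tn[genes].sum()])
        s = np.array([self.ts[genes].sum()])
        ss = np.array([self.tss[genes].sum()])
        bs = np.atleast_1d(self.table.score(n, s, ss))
        return _Module(labels, n, s, ss, bs, len(genes))

    def _row_stats(self, mod: _Module) -> None:
        c = int(mod.labels.max()) + 1
        onehot = np.zeros((self.S, c))
        onehot[np.arange(self.S), mod.labels] = 1.0
        mod.rn = self.mask @ onehot
        mod.rs = self.X0 @ onehot
        mod.rss = self.X2 @ onehot

    # -- gene sweep ----------------------------------------------------------

    def sweep_genes(
        self, rng: np.random.Generator, temperature: float = 1.0, greedy: bool = False
    ) -> int:
        """One Gibbs sweep over genes in randomized order; returns #moves."""
        for mod in self.modules:
            self._row_stats(mod)
        shared_rn = self.tn[:, None]
        shared_rs = self.ts[:, None]
        shared_rss = self.tss[:, None]
        changed = 0
        for g in rng.permutation(self.G):
            src = int(self.module_of[g])
            mod = self.modules[src]
            gn, gs, gss = mod.rn[g], mod.rs[g], mod.rss[g]
            saved = (mod.n.copy(), mod.s.copy(), mod.ss.copy(), mod.bs.copy(), mod.cache)
            # remove gene from its module
            mod.n = mod.n - gn
            mod.s = mod.s - gs
            mod.ss = mod.ss - gss
            mod.bs = np.atleast_1d(self.table.score(mod.n, mod.s, mod.ss))
            removed_cache = float(mod.bs.sum())
            d_remove = removed_cache - saved[4]
            mod.cache = removed_cache
            mod.n_genes -= 1
            # candidate deltas: every module, then one fresh empty module
            n_all, s_all, ss_all, offs, caches = self._concat_stats()
            add_n = np.concatenate([m.rn[g] for m in self.modules])
            add_s = np.concatenate([m.rs[g] for m in self.modules])
            add_ss = np.concatenate([m.rss[g] for m in self.modules])
            after = self.table.score(n_all + add_n, s_all + add_s, ss_all + add_ss)
            deltas = (np.add.reduceat(after, offs) - caches).tolist()
            # exact reversal for the source module (no float drift)
            deltas[src] = saved[4] - removed_cache
            d_fresh = self.table.score1(self.tn[g], self.ts[g], self.tss[g])
            deltas.append(d_fresh)
            k = self._choose(deltas, rng, temperature, greedy)
            if k == src:
                mod.n, mod.s, mod.ss, mod.bs, mod.cache = saved
                mod.n_genes += 1
                self.move_scores.append(self.running_total)
                continue
            changed += 1
            self.running_total += d_remove
            if k == len(self.modules):
                new = _Module(
                    np.zeros(self.S, dtype=np.int64),
                    np.array([self.tn[g]]),
                    np.array([self.ts[g]]),
                    np.array([self.tss[g]]),
                    np.atleast_1d(np.asarray(d_fresh)),
                    1,
                )
                new.rn, new.rs, new.rss = shared_rn, shared_rs, shared_rss
                self.modules.append(new)
                self.running_total += d_fresh
            else:
                tgt = self.modules[k]
                tgt.n = tgt.n + tgt.rn[g]
                tgt.s = tgt.s + tgt.rs[g]
                tgt.ss = tgt.ss + tgt.rss[g]
                tgt.bs = np.atleast_1d(self.table.score(tgt.n, tgt.s, tgt.ss))
                new_cache = float(tgt.bs.sum())
                self.running_total += new_cache - tgt.cache
                tgt.cache = new_cache
                tgt.n_genes += 1
            self.module_of[g] = k
            self.move_scores.append(self.running_total)
        self._collect_empty_modules()
        return changed

    def _concat_stats(self):
        sizes = [len(m.n) for m in self.modules]
        offs = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(np.int64)
        n_all = np.concatenate([m.n for m in self.modules])
        s_all = np.concatenate([m.s for m in self.modules])
        ss_all = np.concatenate([m.ss for m in self.modules])
        caches = np.array([m.cache for m in self.modules])
        return n_all, s_all, ss_all, offs, caches

    @staticmethod
    def _choose(
        deltas: list[float],
        rng: np.random.Generator,
        temperature: float,
        greedy: bool,
    ) -> int:
        if greedy:
            return deltas.index(max(deltas))  # first max: lowest index wins ties
        top = max(deltas)
        weights = [math.exp((d - top) / temperature) for d in deltas]
        r = rng.random() * sum(weights)
        acc = 0.0
        for i, w in enumerate(weights):
            acc += w
            if r < acc:
                return i
        return len(weights) - 1

    def _collect_empty_modules(self) -> None:
        keep = [i for i, m in enumerate(self.modules) if m.n_genes > 0]
        if len(keep) == len(self.modules):
            return
        remap = {old: new for new, old in enumerate(keep)}
        self.modules = [self.modules[i] for i in keep]
        self.module_of = np.array(
            [remap[int(k)] for k in self.module_of], dtype=np.int64
        )

    # -- condition sweep -----------------------------------------------------

    def sweep_conditions(
        self, rng: np.random.Generator, temperature: float = 1.0, greedy: bool = False
    ) -> int:
        """One Gibbs sweep over samples within every module independently."""
        changed = 0
        score1 = self.table.score1
        for j, mod in enumerate(self.modules):
            genes = np.flatnonzero(self.module_of == j)
            if genes.size == 0:
                continue
            cn = self.mask[genes].sum(axis=0).tolist()
            cs = self.X0[genes].sum(axis=0).tolist()
            css = self.X2[genes].sum(axis=0).tolist()
            # cluster stats as plain lists: moves are scalar arithmetic
            lab = mod.labels.tolist()
            ln, ls, lss, lbs = (
                mod.n.tolist(), mod.s.tolist(), mod.ss.tolist(), mod.bs.tolist(),
            )
            for smp in rng.permutation(self.S):
                c0 = lab[smp]
                dn, ds, dss = cn[smp], cs[smp], css[smp]
                saved = (ln[c0], ls[c0], lss[c0], lbs[c0])
                ln[c0] -= dn
                ls[c0] -= ds
                lss[c0] -= dss
                removed_bs = score1(ln[c0], ls[c0], lss[c0])
                d_remove = removed_bs - saved[3]
                lbs[c0] = removed_bs
                deltas = [
                    score1(ln[c] + dn, ls[c] + ds, lss[c] + dss) - lbs[c]
                    for c in range(len(ln))
                ]
                deltas[c0] = saved[3] - removed_bs  # exact reversal
                d_fresh = score1(dn, ds, dss)
                deltas.append(d_fresh)
                c = self._choose(deltas, rng, temperature, greedy)
                if c == c0:
                    ln[c0], ls[c0], lss[c0], lbs[c0] = saved
                    self.move_scores.append(self.running_total)
                    continue
                changed += 1
                self.running_total += d_remove
                if c == len(ln):
                    ln.append(dn)
                    ls.append(ds)
                    lss.append(dss)
                    lbs.append(d_fresh)
                    self.running_total += d_fresh
                else:
                    ln[c] += dn
                    ls[c] += ds
                    lss[c] += dss
                    new_bs = score1(ln[c], ls[c], lss[c])
                    self.running_total += new_bs - lbs[c]
                    lbs[c] = new_bs
                lab[smp] = c
                self.move_scores.append(self.running_total)
            mod.labels = np.asarray(lab, dtype=np.int64)
            mod.n = np.asarray(ln)
            mod.s = np.asarray(ls)
            mod.ss = np.asarray(lss)
            mod.bs = np.asarray(lbs)
            self._collect_empty_clusters(mod)
            mod.cache = float(mod.bs.sum())
        return changed

    @staticmethod
    def _collect_empty_clusters(mod: _Module) -> None:
        used = np.unique(mod.labels)
        if used.size == len(mod.n):
            return
        remap = np.full(len(mod.n), -1, dtype=np.int64)
        remap[used] = np.arange(used.size)
        mod.labels = remap[mod.labels]
        mod.n = mod.n[used]
        mod.s = mod.s[used]
        mod.ss = mod.ss[used]
        mod.bs = mod.bs[used]

    # -- snapshots -----------------------------------------------------------

    def snapshot(self):
        return (
            self.module_of.copy(),
            [m.labels.copy() for m in self.modules],
            self.running_total,
        )

    def to_clustering(self, snapshot=None) -> TwoWayClustering:
        if snapshot is None:
            snapshot = self.snapshot()
        module_of_arr, labels_list, score = snapshot
        gene_ids = self.matrix.gene_ids
        sample_ids = self.matrix.sample_ids
        module_of = {gene_ids[i]: int(module_of_arr[i]) for i in range(self.G)}
        parts: dict[int, dict[str, int]] = {}
        for k, labels in enumerate(labels_list):
            if (module_of_arr == k).any():
                parts[k] = {sample_ids[s]: int(labels[s]) for s in range(self.S)}
        return TwoWayClustering(module_of, parts, float(score))


def sweep_genes(
    state: GibbsState,
    rng: np.random.Generator,
    temperature: float = 1.0,
    greedy: bool = False,
) -> GibbsState:
    state.sweep_genes(rng, temperature, greedy)
    return state


def sweep_conditions(
    state: GibbsState,
    rng: np.random.Generator,
    temperature: float = 1.0,
    greedy: bool = False,
) -> GibbsState:
    state.sweep_conditions(rng, temperature, greedy)
    return state


def run_gibbs(
    matrix: ExpressionMatrix,
    prior: NormalGammaPrior | None = None,
    config: GibbsConfig | None = None,
) -> GibbsResult:
    """Run one seeded two-way clustering chain and return the best state.

    The returned clustering's ``score`` is recomputed from scratch on the
    final partitions, so it is exactly ``total_score`` of the result.
    """
    prior = prior or NormalGammaPrior()
    config = config or GibbsConfig()
    rng = np.random.default_rng(config.seed)
    state = GibbsState(matrix, prior, rng, config.init_modules)
    best = state.snapshot()
    best_score = -math.inf
    sweep_scores: list[float] = []
    temperature = config.temperature
    for sweep in range(config.num_sweeps):
        state.sweep_genes(rng, temperature)
        if config.sample_condition_clusters:
            state.sweep_conditions(rng, temperature)
        sweep_scores.append(state.running_total)
        if sweep >= config.burn_in and state.running_total > best_score:
            best_score = state.running_total
            best = state.snapshot()
        temperature *= config.anneal_factor
    greedy_move_start = len(state.move_scores)
    for _ in range(config.greedy_sweeps):
        moved = state.sweep_genes(rng, greedy=True)
        if config.sample_condition_clusters:
            moved += state.sweep_conditions(rng, greedy=True)
        sweep_scores.append(state.running_total)
        if state.running_total > best_score:
            best_score = state.running_total
            best = state.snapshot()
        if moved == 0:
            break
    clustering = state.to_clustering(best)
    clustering.score = total_score(matrix, clustering, prior)
    return GibbsResult(
        clustering=clustering,
        score=clustering.score,
        sweep_scores=sweep_scores,
        move_scores=state.move_scores,
        n_modules=clustering.n_modules,
        greedy_move_start=greedy_move_start,
    )
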