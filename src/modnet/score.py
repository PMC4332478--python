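"""Bayesian score of a two-way clustering.

Each (module x condition-cluster) block of expression values is modelled as
i.i.d. Normal(mu, 1/tau) with a conjugate normal-gamma prior on (mu, tau):

    mu | tau ~ Normal(mu0, 1/(lambda0 * tau)),   tau ~ Gamma(alpha0, beta0).

Integrating mu and tau out gives the block's closed-form log marginal
likelihood, a function of the block's sufficient statistics (N, mean, sum of
squared deviations) only.  The total score of a clustering is the sum of the
block log marginals over every module and every condition cluster within it;
missing entries contribute nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .io import ExpressionMatrix, TwoWayClustering

LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class NormalGammaPrior:
    """Conjugate normal-gamma prior on the mean and precision of a block.

    The defaults (mu0=0, lambda0=0.1, alpha0=0.1, beta0=0.1) are a weak prior
    appropriate for per-gene centred data; all four are configurable.
    """

    mu0: float = 0.0
    lambda0: float = 0.1
    alpha0: float = 0.1
    beta0: float = 0.1

    def __post_init__(self) -> None:
        for name in ("lambda0", "alpha0", "beta0"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        if not math.isfinite(self.mu0):
            raise ValueError("mu0 must be finite")


@dataclass
class BlockSummary:
    """Sufficient statistics of one data block: N, mean, sum of sq. deviations."""

    n: int
    mean: float
    sum_sq_dev: float

    def __post_init__(self) -> None:
        if self.n < 0 or (self.n > 0 and self.sum_sq_dev < -1e-12):
            raise ValueError("invalid block summary")
        self.sum_sq_dev = max(self.sum_sq_dev, 0.0)

    @classmethod
    def from_values(cls, values) -> "BlockSummary":
        x = np.asarray(values, dtype=float).ravel()
        x = x[~np.isnan(x)]
        if x.size == 0:
            return cls(0, 0.0, 0.0)
        m = float(x.mean())
        return cls(int(x.size), m, float(((x - m) ** 2).sum()))

    def merge(self, other: "BlockSummary") -> "BlockSummary":
        """Pooled summary of the disjoint union of two blocks."""
        if self.n == 0:
            return BlockSummary(other.n, other.mean, other.sum_sq_dev)
        if other.n == 0:
            return BlockSummary(self.n, self.mean, self.sum_sq_dev)
        n = self.n + other.n
        delta = other.mean - self.mean
        mean = self.mean + delta * other.n / n
        ssd = self.sum_sq_dev + other.sum_sq_dev + delta * delta * self.n * other.n / n
        return BlockSummary(n, mean, ssd)


def block_log_marginal(summary: BlockSummary, prior: NormalGammaPrior) -> float:
    """Log marginal likelihood of one block under the normal-gamma model.

    An empty block (N = 0) scores 0 (empty product).
    """
    if not (
        math.isfinite(summary.mean) and math.isfinite(summary.sum_sq_dev)
    ) and summary.n > 0:
        raise ValueError("non-finite block summary")
    n = summary.n
    if n == 0:
        return 0.0
    lam_n = prior.lambda0 + n
    beta_n = (
        prior.beta0
        + 0.5 * summary.sum_sq_dev
        + prior.lambda0 * n * (summary.mean - prior.mu0) ** 2 / (2.0 * lam_n)
    )
    return (
        -0.5 * n * LOG_2PI
        + 0.5 * (math.log(prior.lambda0) - math.log(lam_n))
        + float(gammaln(prior.alpha0 + 0.5 * n) - gammaln(prior.alpha0))
        + prior.alpha0 * math.log(prior.beta0)
        - (prior.alpha0 + 0.5 * n) * math.log(beta_n)
    )


class ScoreTable:
    """Vectorized block scoring with a cached lnGamma(alpha0 + N/2) table.

    Blocks are summarized by raw sums (N, sum, sum of squares); the table makes
    repeated scoring during Gibbs sweeps a pure array computation.
    """

    def __init__(self, prior: NormalGammaPrior, n_max: int):
        self.prior = prior
        self.n_max = int(n_max)
        ns = np.arange(self.n_max + 1)
        self._gl = gammaln(prior.alpha0 + 0.5 * ns)
        self._const = (
            -gammaln(prior.alpha0)
            + prior.alpha0 * math.log(prior.beta0)
            + 0.5 * math.log(prior.lambda0)
        )

    def grow(self, n_max: int) -> None:
        if n_max > self.n_max:
            self.__init__(self.prior, n_max)

    def score1(self, n, s, ss) -> float:
        """Scalar fast path of :meth:`score` for a single block."""
        n = int(n)
        if n == 0:
            return 0.0
        if n > self.n_max:
            self.grow(n * 2)
        p = self.prior
        mean = s / n
        ssd = ss - s * mean
        if ssd < 0.0:
            ssd = 0.0
        lam_n = p.lambda0 + n
        beta_n = p.beta0 + 0.5 * ssd + p.lambda0 * n * (mean - p.mu0) ** 2 / (2.0 * lam_n)
        return float(
            -0.5 * n * LOG_2PI
            - 0.5 * math.log(lam_n)
            + self._gl[n]
            + self._const
            - (p.alpha0 + 0.5 * n) * math.log(beta_n)
        )

    def score(self, n, s, ss):
        """Block log marginal from raw sums; n may be an integer array."""
        n = np.asarray(n, dtype=np.int64)
        s = np.asarray(s, dtype=float)
        ss = np.asarray(ss, dtype=float)
        if n.max(initial=0) > self.n_max:
            self.grow(int(n.max()) * 2)
        p = self.prior
        safe_n = np.maximum(n, 1)
        mean = s / safe_n
        ssd = np.maximum(ss - s * mean, 0.0)
        lam_n = p.lambda0 + n
        beta_n = p.beta0 + 0.5 * ssd + p.lambda0 * n * (mean - p.mu0) ** 2 / (2.0 * lam_n)
        out = (
            -0.5 * n * LOG_2PI
            - 0.5 * np.log(lam_n)
            + self._gl[n]
            + self._const
            - (p.alpha0 + 0.5 * n) * np.log(beta_n)
        )
        return np.where(n == 0, 0.0, out)


def _module_blocks(
    matrix: ExpressionMatrix,
    genes: list[str],
    partition: dict[str, int],
) -> list[BlockSummary]:
    gi = [matrix.gene_index(g) for g in genes]
    labels: dict[int, list[int]] = {}
    for s, c in partition.items():
        labels.setdefault(c, []).append(matrix.sample_index(s))
    return [
        BlockSummary.from_values(matrix.values[np.ix_(gi, cols)])
        for _, cols in sorted(labels.items())
    ]


def total_score(
    matrix: ExpressionMatrix,
    clustering: TwoWayClustering,
    prior: NormalGammaPrior | None = None,
) -> float:
    """Total Bayesian score: sum of block log marginals over all blocks."""
    prior = prior or NormalGammaPrior()
    gene_set = set(matrix.gene_ids)
    sample_set = set(matrix.sample_ids)
    for g in clustering.module_of:
        if g not in gene_set:
            raise KeyError(f"gene {g!r} in clustering but not in matrix")
    total = 0.0
    for k in sorted(set(clustering.module_of.values())):
        genes = clustering.genes_in_module(k)
        part = clustering.condition_partition.get(k)
        if part is None:
            part = {s: 0 for s in matrix.sample_ids}
        for s in part:
            if s not in sample_set:
                raise KeyError(f"sample {s!r} in clustering but not in matrix")
        for summ in _module_blocks(matrix, genes, part):
            total += block_log_marginal(summ, prior)
    return total


def delta_score_gene_move(
    matrix: ExpressionMatrix,
    clustering: TwoWayClustering,
    gene: str,
    target_module: int,
    prior: NormalGammaPrior | None = None,
) -> float:
    """Score change from moving ``gene`` to ``target_module``.

    ``target_module`` may be one past the largest existing index, denoting a
    fresh empty module with the trivial (single-cluster) condition partition.
    Equals ``total_score(after) - total_score(before)`` exactly, but touches
    only the source and target modules.
    """
    prior = prior or NormalGammaPrior()
    modules = sorted(set(clustering.module_of.values()))
    src = clustering.module_of.get(gene)
    if src is None:
        raise KeyError(f"gene {gene!r} not in clustering")
    if target_module not in modules and target_module != max(modules) + 1:
        raise KeyError(f"unknown target module {target_module}")
    if target_module == src:
        return 0.0

    def module_score(k: int, genes: list[str]) -> float:
        if not genes:
            return 0.0
        part = clustering.condition_partition.get(k)
        if part is None:
            part = {s: 0 for s in matrix.sample_ids}
        return sum(block_log_marginal(b, prior) for b in _module_blocks(matrix, genes, part))

    src_genes = clustering.genes_in_module(src)
    tgt_genes = clustering.genes_in_module(target_module)
    delta = 0.0
    delta += module_score(src, [g for g in src_genes if g != gene]) - module_score(
        src, src_genes
    )
    delta += module_score(target_module, tgt_genes + [gene]) - module_score(
        target_module, tgt_genes
    )
    return delta
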