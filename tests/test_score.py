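"""Bayesian block score: quadrature oracle, summaries and incremental moves."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from modnet import (
    BlockSummary,
    NormalGammaPrior,
    TwoWayClustering,
    block_log_marginal,
    delta_score_gene_move,
    total_score,
)
from modnet.score import ScoreTable

LOG2PI = math.log(2 * math.pi)


def quadrature_log_marginal(x, prior) -> float:
    """Independent oracle: 2-D quadrature of the normal-normal-gamma integrand.

    Substitutions tau = exp(t) and mu = mu0 + u/sqrt(lambda0*tau) make the
    integrand smooth and the domain effectively finite; the result is the log
    of the defining double integral, no conjugate algebra involved.
    """
    x = np.asarray(x, float)
    n = x.size
    a0, b0, l0, mu0 = prior.alpha0, prior.beta0, prior.lambda0, prior.mu0
    lgam = math.lgamma(a0)

    def log_f(u, t):
        tau = math.exp(t)
        mu = mu0 + u / math.sqrt(l0 * tau)
        return (
            0.5 * n * (t - LOG2PI)
            - 0.5 * tau * float(((x - mu) ** 2).sum())
            - 0.5 * (LOG2PI + u * u)
            + a0 * math.log(b0)
            - lgam
            + a0 * t
            - b0 * tau
        )

    # center the integrand at its rough grid maximum so quadrature works on
    # an O(1) function regardless of the marginal's magnitude
    scale = max(
        log_f(u, t) for u in np.linspace(-3, 3, 13) for t in np.linspace(-8, 8, 33)
    )
    val, _ = integrate.dblquad(
        lambda u, t: math.exp(log_f(u, t) - scale),
        -180.0, 25.0, -40.0, 40.0, epsabs=1e-12, epsrel=1e-10,
    )
    return scale + math.log(val)


class TestBlockLogMarginal:
    def test_empty_block_scores_zero(self, prior):
        assert block_log_marginal(BlockSummary(0, 0.0, 0.0), prior) == 0.0

    def test_matches_frozen_quadrature_value(self, prior):
        # oracle value for x = {0.3, -1.1, 0.7} under the default prior
        got = block_log_marginal(BlockSummary.from_values([0.3, -1.1, 0.7]), prior)
        assert got == pytest.approx(-7.0587563440, abs=1e-6)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_quadrature_on_random_blocks(self, seed, prior):
        rng = np.random.default_rng(seed)
        for _ in range(2):
            x = rng.uniform(-3, 3, int(rng.integers(1, 11)))
            got = block_log_marginal(BlockSummary.from_values(x), prior)
            assert got == pytest.approx(quadrature_log_marginal(x, prior), abs=1e-6)

    def test_permutation_invariance(self, prior):
        x = [0.1, -2.0, 1.3, 0.4]
        a = block_log_marginal(BlockSummary.from_values(x), prior)
        b = block_log_marginal(BlockSummary.from_values(x[::-1]), prior)
        assert a == pytest.approx(b, rel=1e-12)

    def test_rejects_non_finite_summary(self, prior):
        with pytest.raises(ValueError):
            block_log_marginal(BlockSummary(2, math.inf, 1.0), prior)

    def test_prior_positivity_enforced(self):
        with pytest.raises(ValueError):
            NormalGammaPrior(lambda0=0.0)


class TestBlockSummary:
    @given(
        a=st.lists(st.floats(-5, 5), min_size=0, max_size=12),
        b=st.lists(st.floats(-5, 5), min_size=0, max_size=12),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_merge_equals_concatenation(self, a, b):
        merged = BlockSummary.from_values(a).merge(BlockSummary.from_values(b))
        direct = BlockSummary.from_values(a + b)
        assert merged.n == direct.n
        assert merged.mean == pytest.approx(direct.mean, abs=1e-9)
        assert merged.sum_sq_dev == pytest.approx(direct.sum_sq_dev, abs=1e-8)

    def test_missing_values_excluded(self):
        s = BlockSummary.from_values([1.0, math.nan, 3.0])
        assert s.n == 2 and s.mean == 2.0

    def test_score_table_matches_reference(self, prior):
        rng = np.random.default_rng(1)
        table = ScoreTable(prior, 100)
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(1, 15)))
            ref = block_log_marginal(BlockSummary.from_values(x), prior)
            n, s, ss = len(x), x.sum(), (x**2).sum()
            assert table.score(n, s, ss) == pytest.approx(ref, abs=1e-9)
            assert table.score1(n, s, ss) == pytest.approx(ref, abs=1e-9)


class TestTotalScore:
    def test_single_block_equals_block_marginal(self, small_matrix, prior):
        clustering = TwoWayClustering(
            {g: 0 for g in small_matrix.gene_ids},
            {0: {s: 0 for s in small_matrix.sample_ids}},
        )
        expected = block_log_marginal(
            BlockSummary.from_values(small_matrix.values), prior
        )
        assert total_score(small_matrix, clustering, prior) == pytest.approx(expected)

    def test_singleton_modules_sum_per_gene(self, small_matrix, prior):
        clustering = TwoWayClustering(
            {g: i for i, g in enumerate(small_matrix.gene_ids)},
            {
                i: {s: 0 for s in small_matrix.sample_ids}
                for i in range(small_matrix.n_genes)
            },
        )
        expected = sum(
            block_log_marginal(BlockSummary.from_values(row), prior)
            for row in small_matrix.values
        )
        assert total_score(small_matrix, clustering, prior) == pytest.approx(expected)

    def test_splitting_two_mean_conditions_raises_score(self, prior):
        from modnet import ExpressionMatrix

        rng = np.random.default_rng(2)
        vals = np.hstack(
            [rng.normal(2.0, 0.2, (6, 8)), rng.normal(-2.0, 0.2, (6, 8))]
        )
        m = ExpressionMatrix(
            [f"g{i}" for i in range(6)], [f"s{j}" for j in range(16)], vals
        )
        merged = TwoWayClustering(
            {g: 0 for g in m.gene_ids}, {0: {s: 0 for s in m.sample_ids}}
        )
        split = TwoWayClustering(
            {g: 0 for g in m.gene_ids},
            {0: {s: int(j >= 8) for j, s in enumerate(m.sample_ids)}},
        )
        assert total_score(m, split, prior) > total_score(m, merged, prior)

    def test_relabeling_invariance(self, small_matrix, random_clustering, prior):
        base = total_score(small_matrix, random_clustering, prior)
        relabeled = TwoWayClustering(
            {g: 2 - k for g, k in random_clustering.module_of.items()},
            {
                2 - k: {s: 1 - c for s, c in part.items()}
                for k, part in random_clustering.condition_partition.items()
            },
        )
        assert total_score(small_matrix, relabeled, prior) == pytest.approx(base)

    def test_unknown_gene_rejected(self, small_matrix, prior):
        clustering = TwoWayClustering({"nope": 0}, {0: {}})
        with pytest.raises(KeyError):
            total_score(small_matrix, clustering, prior)


class TestDeltaScore:
    def test_agrees_with_full_recomputation(self, small_matrix, random_clustering, prior):
        rng = np.random.default_rng(7)
        before = total_score(small_matrix, random_clustering, prior)
        for _ in range(100):
            gene = small_matrix.gene_ids[int(rng.integers(small_matrix.n_genes))]
            target = int(rng.integers(0, 3))
            delta = delta_score_gene_move(
                small_matrix, random_clustering, gene, target, prior
            )
            moved = TwoWayClustering(
                {**random_clustering.module_of, gene: target},
                random_clustering.condition_partition,
            )
            after = total_score(small_matrix, moved, prior)
            assert delta == pytest.approx(after - before, abs=1e-9)

    def test_move_to_own_module_is_zero(self, small_matrix, random_clustering, prior):
        gene = small_matrix.gene_ids[0]
        k = random_clustering.module_of[gene]
        assert delta_score_gene_move(small_matrix, random_clustering, gene, k, prior) == 0.0

    def test_fresh_module_delta_is_gene_score_alone(self, small_matrix, prior):
        clustering = TwoWayClustering(
            {g: 0 for g in small_matrix.gene_ids},
            {0: {s: 0 for s in small_matrix.sample_ids}},
        )
        gene = small_matrix.gene_ids[3]
        delta = delta_score_gene_move(small_matrix, clustering, gene, 1, prior)
        gi = small_matrix.gene_index(gene)
        alone = block_log_marginal(
            BlockSummary.from_values(small_matrix.values[gi]), prior
        )
        others = TwoWayClustering(
            {g: 0 for g in small_matrix.gene_ids if g != gene},
            {0: {s: 0 for s in small_matrix.sample_ids}},
        )
        all_score = total_score(small_matrix, clustering, prior)
        others_score = total_score(small_matrix, others, prior)
        assert delta == pytest.approx(others_score + alone - all_score, abs=1e-9)

    def test_unknown_target_module_rejected(self, small_matrix, random_clustering, prior):
        with pytest.raises(KeyError):
            delta_score_gene_move(
                small_matrix, random_clustering, small_matrix.gene_ids[0], 99, prior
            )
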