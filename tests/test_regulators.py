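"""Regulator split scoring, posteriors, consensus scores, null and ranking."""

import math

import numpy as np
import pytest
from scipy.special import log_expit

from modnet import (
    RegulatorMatrix,
    assign_regulators,
    build_null,
    consensus_score,
    hub_scores,
    score_split,
    select_top_fraction,
)
from modnet.io import ConditionTree, TreeNode
from modnet.regulators import RegulatorAssignment


def brute_force_split(values, left, right, beta):
    """Exhaustive scan over all midpoints and both orientations."""
    xs = sorted({values[s] for s in list(left) + list(right)})
    candidates = [0.5 * (a + b) for a, b in zip(xs, xs[1:])] or [xs[0]]
    best = (-math.inf, None, None)
    for z in candidates:
        for orient in (1, -1):
            ll = 0.0
            for s in right:
                ll += float(log_expit(orient * beta * (values[s] - z)))
            for s in left:
                ll += float(log_expit(-orient * beta * (values[s] - z)))
            if ll > best[0]:
                best = (ll, z, orient)
    return best


class TestScoreSplit:
    def test_perfect_separator_has_near_zero_loglik(self):
        values = {f"l{i}": -2.0 - i for i in range(5)}
        values.update({f"r{i}": 2.0 + i for i in range(5)})
        fit = score_split(values, [f"l{i}" for i in range(5)], [f"r{i}" for i in range(5)], beta=10.0)
        assert fit.orientation == 1
        assert -1e-3 < fit.loglik <= 0.0
        assert -2.0 < fit.split_value < 2.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(4)
        for trial in range(10):
            samples = [f"s{i}" for i in range(12)]
            values = {s: float(rng.normal()) for s in samples}
            left, right = samples[:6], samples[6:]
            fit = score_split(values, left, right, beta=5.0)
            ll, z, orient = brute_force_split(values, left, right, 5.0)
            assert fit.loglik == pytest.approx(ll, abs=1e-9)

    def test_one_sample_each_side_equal_values(self):
        fit = score_split({"a": 1.0, "b": 1.0}, ["a"], ["b"])
        assert fit.loglik == pytest.approx(2 * math.log(0.5))

    def test_constant_regulator_valid_but_low(self):
        values = {f"s{i}": 0.7 for i in range(6)}
        fit = score_split(values, [f"s{i}" for i in range(3)], [f"s{i}" for i in range(3, 6)])
        assert fit.split_value == 0.7
        assert fit.loglik == pytest.approx(6 * math.log(0.5))

    def test_overlapping_sides_rejected(self):
        with pytest.raises(ValueError):
            score_split({"a": 1.0}, ["a"], ["a"])

    def test_missing_samples_skipped(self):
        values = {"a": -1.0, "b": 1.0}  # "c" absent
        fit = score_split(values, ["a"], ["b", "c"], beta=10.0)
        full = score_split(values, ["a"], ["b"], beta=10.0)
        assert fit.loglik == pytest.approx(full.loglik)


def toy_trees(levels=(0, 1)):
    """One module, one tree: root split plus one nested split."""
    inner = TreeNode(left=TreeNode(samples=["s0", "s1"]), right=TreeNode(samples=["s2"]))
    root = TreeNode(left=inner, right=TreeNode(samples=["s3", "s4", "s5"]))
    return {0: [ConditionTree(0, root)]}


class TestPosteriors:
    def test_identical_candidates_split_posterior_evenly(self):
        samples = [f"s{i}" for i in range(6)]
        vals = np.array([[-1, -1, -1, 1, 1, 1.0]] * 2)
        regs = RegulatorMatrix(["rA", "rB"], samples, vals)
        assignments = assign_regulators(toy_trees(), regs)
        by_node: dict[str, list[RegulatorAssignment]] = {}
        for a in assignments:
            by_node.setdefault(a.node_id, []).append(a)
        for node_assignments in by_node.values():
            for a in node_assignments:
                assert a.posterior == pytest.approx(0.5, abs=1e-12)

    def test_posteriors_sum_to_one_at_every_node(self):
        rng = np.random.default_rng(6)
        samples = [f"s{i}" for i in range(6)]
        regs = RegulatorMatrix(
            [f"r{i}" for i in range(8)], samples, rng.normal(size=(8, 6))
        )
        assignments = assign_regulators(toy_trees(), regs)
        sums: dict[str, float] = {}
        for a in assignments:
            sums[a.node_id] = sums.get(a.node_id, 0.0) + a.posterior
        assert len(sums) == 2
        for total in sums.values():
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_planted_separator_beats_noise_regulators(self, benchmark_data):
        matrix, regs, truth = benchmark_data
        wins = 0
        total = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            module = 0
            part = truth.condition_partition[module]
            left = [s for s in matrix.sample_ids if part[s] == 0]
            right = [s for s in matrix.sample_ids if part[s] == 1]
            node = TreeNode(
                left=TreeNode(samples=left), right=TreeNode(samples=right)
            )
            trees = {0: [ConditionTree(0, node)]}
            # fresh noise regulators each replicate, planted one kept
            planted_row = regs.values[regs.regulator_ids.index(truth.planted_regulator[module])]
            noise = rng.normal(size=(49, matrix.n_samples))
            rm = RegulatorMatrix(
                ["planted"] + [f"n{i}" for i in range(49)],
                list(matrix.sample_ids),
                np.vstack([planted_row, noise]),
            )
            assignments = assign_regulators(trees, rm)
            best = max(assignments, key=lambda a: a.posterior)
            total += 1
            wins += best.regulator_id == "planted"
        assert wins >= 18  # >= 90% of replicates


class TestConsensusScore:
    def test_single_root_assignment(self):
        a = RegulatorAssignment("r", 3, "n", 0.0, 1, 1.0, level=0)
        assert consensus_score([a]) == {("r", 3): 1.0}

    def test_ten_trees_at_root(self):
        assignments = [
            RegulatorAssignment("r", 0, f"t{i}", 0.0, 1, 0.8, level=0)
            for i in range(10)
        ]
        assert consensus_score(assignments)[("r", 0)] == pytest.approx(8.0)

    def test_mixed_depth_matches_hand_enumeration(self):
        assignments = [
            RegulatorAssignment("r", 0, "a", 0, 1, 0.5, level=0),
            RegulatorAssignment("r", 0, "b", 0, 1, 0.25, level=1),
            RegulatorAssignment("r", 0, "c", 0, 1, 1.0, level=2),
            RegulatorAssignment("q", 0, "a", 0, 1, 0.5, level=0),
            RegulatorAssignment("r", 1, "d", 0, 1, 0.3, level=1),
        ]
        scores = consensus_score(assignments)
        assert scores[("r", 0)] == pytest.approx(0.5 + 0.25 / 2 + 1.0 / 4)
        assert scores[("q", 0)] == pytest.approx(0.5)
        assert scores[("r", 1)] == pytest.approx(0.15)

    def test_adding_supporting_tree_never_decreases_score(self):
        base = [RegulatorAssignment("r", 0, "a", 0, 1, 0.4, level=1)]
        extra = base + [RegulatorAssignment("r", 0, "b", 0, 1, 0.2, level=2)]
        assert consensus_score(extra)[("r", 0)] >= consensus_score(base)[("r", 0)]


class TestNull:
    def test_reproducible_and_nonnegative(self):
        rng = np.random.default_rng(2)
        samples = [f"s{i}" for i in range(6)]
        regs = RegulatorMatrix(
            [f"r{i}" for i in range(5)], samples, rng.normal(size=(5, 6))
        )
        trees = toy_trees()
        a = build_null(regs, trees, n_draws=50, seed=9)
        b = build_null(regs, trees, n_draws=50, seed=9)
        np.testing.assert_array_equal(a.draws, b.draws)
        assert (a.draws >= 0).all()
        assert a.size == 50


class TestSelectionAndHubs:
    def test_top_fraction_counts(self):
        scores = {(f"r{i}", 0): float(i) for i in range(1000)}
        kept, regs = select_top_fraction(scores, 0.01)
        assert len(kept) == 10
        assert min(s for s in kept.values()) == 990.0

    def test_ties_at_cut_kept(self):
        scores = {(f"r{i}", 0): 1.0 for i in range(20)}
        kept, _ = select_top_fraction(scores, 0.1)
        assert len(kept) == 20

    def test_scores_1_to_100_fraction_5pct(self):
        scores = {(f"r{i}", 0): float(i) for i in range(1, 101)}
        kept, _ = select_top_fraction(scores, 0.05)
        assert sorted(s for s in kept.values()) == [96.0, 97.0, 98.0, 99.0, 100.0]

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            select_top_fraction({}, 0.01)

    def test_hub_aggregation_and_ranking(self):
        selected = {
            ("a", 0): 2.0, ("a", 1): 3.0,
            ("b", 0): 4.0,
            ("c", 0): 1.0, ("c", 1): 1.0, ("c", 2): 1.0,
        }
        ranked = hub_scores(selected)
        assert ranked[0] == ("a", 2, pytest.approx(5.0))
        assert ranked[1] == ("b", 1, pytest.approx(4.0))
        assert ranked[2] == ("c", 3, pytest.approx(3.0))

    def test_toy_table_matches_hand_ranking(self):
        rng = np.random.default_rng(0)
        scores = {
            (r, m): round(float(rng.uniform(0, 10)), 3)
            for r in "abcde" for m in range(3)
        }
        ranked = hub_scores(scores)
        sums = {r: sum(scores[(r, m)] for m in range(3)) for r in "abcde"}
        assert [r for r, _, _ in ranked] == sorted(sums, key=lambda r: -sums[r])
        for r, nm, tot in ranked:
            assert nm == 3
            assert tot == pytest.approx(sums[r])
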