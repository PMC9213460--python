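from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import treeplan as tp
from treeplan.engine import (
    ROLE_ACTION,
    ValueDistribution,
    diffusion_step,
    heterogeneous_values,
    initial_level_distribution,
    maximization_step,
    tree_value,
)
from treeplan.policies import TWO_B, PolicySpec


def make_q_dist(table, scale=1, depth=1):
    lo, hi = min(table), max(table)
    probs = np.zeros(hi - lo + 1)
    for k, p in table.items():
        probs[k - lo] = p
    return ValueDistribution(probs, lo=lo, scale=scale, depth=depth,
                            role=ROLE_ACTION)


class TestInitialLevel:
    def test_nothing_sampled_is_point_mass_at_zero(self, rich1):
        dist = initial_level_distribution(rich1, 0.0, 5)
        assert dist.as_dict() == {0: 1.0}

    def test_fully_sampled_two_branches(self, rich1):
        # P(J1=1) = 1 - 2^-b at b=2
        dist = initial_level_distribution(rich1, 1.0, 2)
        assert dist.probability_of(1) == pytest.approx(0.75, abs=1e-15)
        assert dist.probability_of(-1) == pytest.approx(0.25, abs=1e-15)

    def test_half_sampled_two_branches(self, rich1):
        dist = initial_level_distribution(rich1, 0.5, 2)
        assert dist.probability_of(1) == pytest.approx(0.4375, abs=1e-15)
        assert dist.probability_of(0) == pytest.approx(0.5, abs=1e-15)
        assert dist.probability_of(-1) == pytest.approx(0.0625, abs=1e-15)

    def test_generic_model_rejected(self):
        generic = tp.make_reward_model("generic", 0.4)
        with pytest.raises(ValueError):
            initial_level_distribution(generic, 1.0, 2)


class TestDiffusion:
    def test_no_sample_no_death_is_identity(self, rich1):
        prior = maximization_step(make_q_dist({1: 0.6, -1: 0.4}), 1)
        out = diffusion_step(rich1, prior, q=0.0, gamma=1.0)
        assert out.as_dict() == {1: 0.6, -1: 0.4}
        assert out.role == ROLE_ACTION and out.depth == prior.depth + 1

    def test_point_mass_splits_half_half(self, rich1):
        prior = maximization_step(make_q_dist({3: 1.0}), 1)
        out = diffusion_step(rich1, prior, q=1.0, gamma=1.0)
        assert out.as_dict() == {2: 0.5, 4: 0.5}

    def test_dead_agent_keeps_only_immediate_reward(self, rich1):
        prior = maximization_step(make_q_dist({5: 0.3, 1: 0.7}), 1)
        out = diffusion_step(rich1, prior, q=1.0, gamma=0.0)
        assert out.as_dict() == {1: 0.5, -1: 0.5}

    def test_scale_mismatch_rejected(self, rich1):
        prior = maximization_step(make_q_dist({1: 1.0}, scale=3), 1)
        with pytest.raises(ValueError, match="scale"):
            diffusion_step(rich1, prior, q=1.0)


class TestMaximization:
    def test_single_branch_is_identity(self):
        qdist = make_q_dist({2: 0.375, 0: 0.5, -2: 0.125})
        out = maximization_step(qdist, 1)
        assert out.as_dict() == pytest.approx(qdist.as_dict())

    def test_two_branch_coin(self):
        out = maximization_step(make_q_dist({1: 0.5, -1: 0.5}), 2)
        assert out.as_dict() == pytest.approx({1: 0.75, -1: 0.25})

    def test_best_of_two_three_point(self):
        # brute force over the 3^2 ordered pairs of iid draws
        qdist = make_q_dist({2: 3 / 8, 0: 1 / 2, -2: 1 / 8})
        out = maximization_step(qdist, 2)
        assert out.as_dict() == pytest.approx(
            {2: 39 / 64, 0: 24 / 64, -2: 1 / 64}, abs=1e-15
        )

    def test_cdf_power_identity(self):
        qdist = make_q_dist({3: 0.2, 1: 0.3, 0: 0.1, -2: 0.4})
        for b in (2, 3, 5):
            out = maximization_step(qdist, b)
            np.testing.assert_allclose(
                np.cumsum(out.probs), np.cumsum(qdist.probs) ** b, atol=1e-14
            )


class TestTreeValue:
    @pytest.mark.parametrize("b", range(1, 7))
    def test_depth_one_closed_form(self, rich1, b):
        # V_1 = 1 - 2^(1-b) for p = 1/2
        result = tree_value(rich1, tp.exhaustive_policy(b, 1))
        assert result.value == pytest.approx(1 - 2.0 ** (1 - b), abs=1e-14)

    def test_exhaustive_depth_two(self, rich1):
        result = tree_value(rich1, tp.exhaustive_policy(2, 2))
        assert result.value == pytest.approx(19 / 16, abs=1e-14)

    @pytest.mark.parametrize("C", [3, 10, 47])
    def test_single_branch_policy_is_worthless(self, rich1, C):
        # no freedom to choose a path => expected cumulative reward zero
        assert tree_value(rich1, tp.homogeneous_policy(1, C)).value == 0.0

    def test_all_zero_q_has_zero_value(self, rich1):
        pol = tp.heterogeneous_policy(3, (Fraction(0),) * 4)
        assert tree_value(rich1, pol).value == 0.0

    def test_value_equals_terminal_mean(self, poor99):
        result = tree_value(poor99, tp.homogeneous_policy(3, 10))
        keys = result.terminal.keys()
        manual = float(keys @ result.terminal.probs) / result.terminal.scale
        assert result.value == manual

    def test_generic_model_rejected(self):
        generic = tp.make_reward_model("generic", 0.4)
        with pytest.raises(ValueError):
            tree_value(generic, tp.exhaustive_policy(2, 2))


class TestReductions:
    @pytest.mark.parametrize("b,d", [(2, 3), (3, 2), (1, 4)])
    def test_all_one_selective_equals_exhaustive(self, rich1, b, d):
        selective = tp.heterogeneous_policy(b, (Fraction(1),) * d)
        v1 = tree_value(rich1, selective).value
        v2 = tree_value(rich1, tp.exhaustive_policy(b, d)).value
        assert v1 == pytest.approx(v2, abs=1e-14)

    @pytest.mark.parametrize("b", [1, 2, 3])
    def test_two_b_with_equal_branches_equals_single_b(self, rich1, b):
        q = (Fraction(1, 4),) + (Fraction(1),) * 3
        single = tp.heterogeneous_policy(b, q)
        double = PolicySpec(TWO_B, q=q, b1=b, b2=b, d1=2, d2=2)
        assert tree_value(rich1, double).value == pytest.approx(
            tree_value(rich1, single).value, abs=1e-14
        )

    def test_two_b_with_empty_second_regime_equals_single_b(self, rich1):
        q = (Fraction(1, 2),) + (Fraction(1),) * 2
        single = tp.heterogeneous_policy(2, q)
        double = PolicySpec(TWO_B, q=q, b1=2, b2=7, d1=3, d2=0)
        assert tree_value(rich1, double).value == pytest.approx(
            tree_value(rich1, single).value, abs=1e-14
        )

    def test_survival_one_equals_undiscounted(self, poor99):
        q = (Fraction(3, 4), Fraction(1), Fraction(1, 2))
        undiscounted = tp.heterogeneous_policy(2, q)
        discounted = tp.heterogeneous_policy(2, q, gamma=1.0)
        assert tree_value(poor99, discounted).value == tree_value(
            poor99, undiscounted
        ).value

    def test_survival_zero_reduces_to_top_level_only(self, rich1):
        # with certain death only the first level's reward is ever seen
        q = (Fraction(1, 8), Fraction(3, 4), Fraction(1, 2))
        dead = tp.heterogeneous_policy(2, q, gamma=0.0)
        one_level = tp.heterogeneous_policy(2, (q[-1],))
        assert tree_value(rich1, dead).value == pytest.approx(
            tree_value(rich1, one_level).value, abs=1e-14
        )


class TestInvariantsAndBounds:
    def test_terminal_mass_sums_to_one(self, rich1, poor99):
        for model, pol in [
            (rich1, tp.homogeneous_policy(2, 100)),
            (poor99, tp.homogeneous_policy(5, 50)),
            (rich1, tp.homogeneous_policy(2, 100, gamma=0.9)),
        ]:
            total = tree_value(model, pol).terminal.probs.sum()
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_exhaustive_value_monotone_in_depth_and_breadth(self, rich1):
        grid = {
            (b, d): tree_value(rich1, tp.exhaustive_policy(b, d)).value
            for b in range(1, 5)
            for d in range(1, 7)
        }
        for (b, d), v in grid.items():
            assert v <= d + 1e-12  # diagonal bound: no tree beats +1 per level
            if (b, d - 1) in grid:
                assert v >= grid[b, d - 1] - 1e-12
            if (b - 1, d) in grid:
                assert v >= grid[b - 1, d] - 1e-12

    @settings(deadline=None, max_examples=25)
    @given(st.data())
    def test_value_monotone_in_q(self, rich1, data):
        d = data.draw(st.integers(2, 5), label="depth")
        q = data.draw(
            st.lists(st.floats(0.05, 0.95), min_size=d, max_size=d), label="q"
        )
        level = data.draw(st.integers(0, d - 1), label="level")
        bump = data.draw(st.floats(0.01, 1.0), label="bump")
        q2 = list(q)
        q2[level] = min(1.0, q2[level] + bump)
        v1 = tree_value(rich1, tp.heterogeneous_policy(2, tuple(q))).value
        v2 = tree_value(rich1, tp.heterogeneous_policy(2, tuple(q2))).value
        assert v2 >= v1 - 1e-10

    @pytest.mark.parametrize("model_name, n", [("rich", 1), ("rich", 2), ("poor", 2)])
    def test_support_size_matches_state_count(self, model_name, n):
        # strictly interior q populates every admissible lattice state
        model = tp.make_reward_model(model_name, n)
        d = 6
        pol = tp.heterogeneous_policy(2, (Fraction(1, 2),) * d)
        terminal = tree_value(model, pol).terminal
        assert terminal.support_size() == tp.distinct_state_count(n, d)

    def test_deep_tree_runs_fast_and_normalized(self, rich1):
        # d=20, b=5 stands in for a sub-tree of ~1.2e14 nodes
        result = tree_value(rich1, tp.exhaustive_policy(5, 20))
        assert result.terminal.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert 0 < result.value <= 20


class TestBatchedEvaluation:
    def test_batch_matches_per_policy_values(self, rich1):
        rng = np.random.default_rng(7)
        Q = rng.uniform(0, 1, size=(8, 5))
        batch = heterogeneous_values(rich1, 3, Q)
        for i in range(len(Q)):
            pol = tp.heterogeneous_policy(3, tuple(Q[i]))
            assert batch[i] == pytest.approx(
                tree_value(rich1, pol).value, abs=1e-12
            )

    def test_batch_matches_discounted_values(self, rich1):
        rng = np.random.default_rng(11)
        Q = rng.uniform(0, 1, size=(4, 4))
        batch = heterogeneous_values(rich1, 2, Q, gamma=0.8)
        for i in range(len(Q)):
            pol = tp.heterogeneous_policy(2, tuple(Q[i]), gamma=0.8)
            assert batch[i] == pytest.approx(
                tree_value(rich1, pol).value, abs=1e-12
            )
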