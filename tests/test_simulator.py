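from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from innovurn import (
    LiteralUrnSystem,
    SystemState,
    enumerate_paths,
    exact_probabilities,
    expected_dstar_recursion,
    literal_probabilities,
    normalize,
    poisson_dirichlet,
    simulate,
)
from conftest import make_random_normalized, make_random_raw


def forced_t1_state(params) -> SystemState:
    """State after the (deterministic) first step: every agent a novelty."""
    state = SystemState(params)
    state.step(np.random.default_rng(0))
    assert state.t == 1 and state.n_colors == params.N
    return state


class TestProbabilities:
    def test_birth_probability_is_one_at_time_zero(self, worked_example):
        state = SystemState(worked_example)
        for h in range(2):
            assert state.new_probability(h) == 1.0
        assert state.old_color_distribution(0) == {}

    def test_worked_example_hand_numbers(self, worked_example):
        state = forced_t1_state(worked_example)
        assert state.new_probability(0) == pytest.approx(0.65)
        dist = state.old_color_distribution(0)
        assert dist[0] == pytest.approx(0.25)
        assert dist[1] == pytest.approx(0.10)
        assert state.new_probability(0) + sum(dist.values()) == pytest.approx(1.0)

    def test_reduces_to_pitman_yor_for_single_agent(self):
        p = poisson_dirichlet(1, Fraction(1, 2))
        state = SystemState(p)
        rng = np.random.default_rng(3)
        for _ in range(30):
            state.step(rng)
            D, t = state.n_colors, state.t
            assert state.new_probability(0) == pytest.approx((1 + 0.5 * D) / (1 + t))
            for c, pc in state.old_color_distribution(0).items():
                k = state.counts[0, c]
                assert pc == pytest.approx((k - 0.5) / (1 + t))

    def test_invalid_agent_index(self, worked_example):
        state = SystemState(worked_example)
        with pytest.raises(IndexError):
            state.new_probability(2)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), n=st.integers(1, 4))
    def test_normalization_identity_on_random_states(self, seed, n):
        rng = np.random.default_rng(seed)
        params = make_random_normalized(rng, n)
        state = SystemState(params)
        for _ in range(rng.integers(1, 50)):
            state.step(rng)
        for h in range(n):
            total = state.new_probability(h) + state.old_color_probabilities(h).sum()
            assert total == pytest.approx(1.0, abs=1e-12)


class TestStep:
    def test_first_step_all_novelties_distinct_ids(self, random_normalized):
        rng = np.random.default_rng(9)
        params = random_normalized(rng, 4)
        state = SystemState(params)
        colors, is_new = state.step(rng)
        assert is_new.all()
        assert sorted(colors.tolist()) == [0, 1, 2, 3]

    def test_simultaneous_novelties_never_share_ids(self, worked_example):
        rng = np.random.default_rng(11)
        state = SystemState(worked_example)
        for _ in range(200):
            colors, is_new = state.step(rng)
            if is_new.sum() >= 2:
                assert len(set(colors[is_new].tolist())) == int(is_new.sum())

    def test_same_seed_identical_trajectories(self, worked_example):
        a = simulate(worked_example, T=200, seed=42)
        b = simulate(worked_example, T=200, seed=42)
        np.testing.assert_array_equal(a.color, b.color)
        np.testing.assert_array_equal(a.is_new, b.is_new)

    def test_invariants_hold_along_a_run(self, random_normalized):
        rng = np.random.default_rng(17)
        params = random_normalized(rng, 3)
        state = SystemState(params)
        for _ in range(100):
            state.step(rng)
            state.check_invariants()

    def test_one_step_frequencies_match_closed_form(self, worked_example):
        # from the forced t=1 state, agent 1 sees (new, c0, c1) w.p. (.65,.25,.10)
        n_rep = 20000
        counts = {"new": 0, 0: 0, 1: 0}
        rng = np.random.default_rng(123)
        for _ in range(n_rep):
            state = forced_t1_state(worked_example)
            colors, is_new = state.step(rng)
            key = "new" if is_new[0] else int(colors[0])
            counts[key] += 1
        for key, p in (("new", 0.65), (0, 0.25), (1, 0.10)):
            se = np.sqrt(p * (1 - p) / n_rep)
            assert abs(counts[key] / n_rep - p) < 4 * se

    def test_nonpositive_horizon_rejected(self, worked_example):
        with pytest.raises(ValueError):
            simulate(worked_example, T=0, seed=1)


class TestMeanRecursion:
    def test_hand_iterated_values(self):
        p0 = poisson_dirichlet(1, 0)
        e = expected_dstar_recursion(p0, 3)
        assert e[1, 0] == pytest.approx(1.0)
        assert e[2, 0] == pytest.approx(1.5)
        assert e[3, 0] == pytest.approx(1.5 + 1 / 3)
        p5 = poisson_dirichlet(1, Fraction(1, 2))
        e5 = expected_dstar_recursion(p5, 2)
        assert e5[1, 0] == pytest.approx(1.0)
        assert e5[2, 0] == pytest.approx(1.75)

    def test_monte_carlo_mean_matches_recursion(self, worked_example):
        T, n_rep = 200, 200
        exact = expected_dstar_recursion(worked_example, T)
        finals = np.empty((n_rep, 2))
        for k in range(n_rep):
            traj = simulate(worked_example, T=T, seed=1000 + k)
            finals[k] = traj.state.dstar
        se = finals.std(axis=0, ddof=1) / np.sqrt(n_rep)
        assert np.all(np.abs(finals.mean(axis=0) - exact[T]) < 3 * se)


class TestLiteralOracle:
    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), n=st.integers(1, 3))
    def test_literal_probabilities_equal_closed_form_exactly(self, seed, n):
        rng = np.random.default_rng(seed)
        raw = make_random_raw(rng, n)
        params = normalize(raw)
        traj = simulate(params, T=50, seed=seed % 977)
        state = traj.state
        lit = literal_probabilities(raw, traj)
        for h in range(n):
            newp, old = exact_probabilities(
                params,
                state.counts.tolist(),
                state.originators.tolist(),
                state.t,
                h,
            )
            assert lit[h][0] == newp
            for c, pc in enumerate(old):
                assert lit[h][1].get(c, Fraction(0)) == pc

    def test_old_extraction_adds_rho_balls_per_source(self):
        raw = RawParamsFactory()
        sys = LiteralUrnSystem(raw)
        sys.apply_step([0, 1], [True, True])
        before = [dict(b) for b in sys.balls]
        sys.apply_step([0, 0], [False, False])  # both urns re-draw color 0
        for h in range(2):
            gained = sys.balls[h][0] - before[h].get(0, 0)
            assert gained == int(raw.rho[0, h]) + int(raw.rho[1, h])


def RawParamsFactory():
    from innovurn import RawParams

    return RawParams(
        N0=[3, 2],
        rho_hat=[[2, 1], [1, 3]],
        nu=[[1, 1], [1, 1]],
        rho=[[3, 2], [2, 4]],
    )


class TestEnumeration:
    def test_outcome_tree_probabilities_sum_to_one(self, worked_example):
        paths = enumerate_paths(worked_example, 3)
        assert sum(p for _, p in paths) == 1
        assert all(p > 0 for _, p in paths)

    def test_path_probabilities_match_literal_urn_products(self, worked_example):
        """Dual route: exact-engine path probabilities vs integer ball counts."""
        raw = denorm_worked(worked_example)
        paths = enumerate_paths(worked_example, 2)
        for events, prob in paths:
            sys = LiteralUrnSystem(raw)
            lit_prob = Fraction(1)
            for step_events in events:
                probs = [sys.probabilities(h) for h in range(2)]
                for h, (c, is_new) in enumerate(step_events):
                    newp, old = probs[h]
                    lit_prob *= newp if is_new else old[c]
                sys.apply_step(
                    [c for c, _ in step_events], [isn for _, isn in step_events]
                )
            assert lit_prob == prob


def denorm_worked(params):
    from innovurn import denormalize

    return denormalize(params, [10, 10])
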