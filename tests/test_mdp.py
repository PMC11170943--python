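"""MDP engine: state space, outcome posteriors, transitions, solver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tokenmdp.mdp import (
    build_transition_model,
    enumerate_states,
    mdp_choice_prob,
    outcome_posterior,
    value_iteration,
    value_iteration_dense,
)
from tokenmdp.task import TaskConfig

from _mini import MINI, mini_curves, mini_dense_mdp

class TestStateSpace:
    def test_full_grid_size(self, config):
        assert len(enumerate_states(config)) == 13 * 6 * 10 * 18 == 14040

    def test_bounds_match_task_ranges(self, config):
        states = enumerate_states(config)
        assert {s.ntk for s in states} == set(range(13))
        assert {s.tsco for s in states} == set(range(1, 7))
        assert {s.te for s in states} == set(range(1, 11))
        assert {s.nobs for s in states} == set(range(1, 19))

    def test_pruning_removes_unreachable_token_counts(self, config):
        pruned = enumerate_states(config, prune_infeasible=True)
        assert not any(s.ntk == 8 and s.tsco == 1 for s in pruned)
        assert all(s.ntk <= 2 * s.tsco for s in pruned)
        # two completed trials can yield at most four tokens
        assert max(s.ntk for s in pruned if s.tsco == 2) == 4


class TestOutcomePosterior:
    def test_early_learning_worked_example(self):
        p = outcome_posterior(np.array([0.17, 0.11, -0.01, -0.01]), 0.175, 0)
        assert round(float(p[0]), 2) == 0.24

    def test_late_learning_worked_example(self):
        p = outcome_posterior(np.array([0.66, 0.36, -0.03, -0.04]), 0.23, 0)
        assert round(float(p[0]), 2) == 0.52

    def test_uniform_when_means_tied(self):
        p = outcome_posterior(np.zeros(4), 0.5, 2)
        assert np.allclose(p, [0.1875, 0.1875, 0.25, 0.1875, 0.1875])

    def test_degenerate_sigma_rejected(self):
        with pytest.raises(ValueError):
            outcome_posterior(np.zeros(4), 0.0, 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        mus=st.lists(st.floats(-1, 1), min_size=4, max_size=4),
        sigma=st.floats(0.05, 1.0),
        choice=st.integers(0, 3),
    )
    def test_normalization_and_delivery_split(self, mus, sigma, choice):
        p = outcome_posterior(np.array(mus), sigma, choice)
        assert p.sum() == pytest.approx(1.0)
        assert p[2] == 0.25
        # the non-zero outcomes share the 0.75 delivery mass; a posterior
        # can saturate to 0.75 at float precision under extreme separation
        assert np.all(p >= 0) and np.all(p[[0, 1, 3, 4]] <= 0.75)


class TestTransitionModel:
    def test_rows_normalized_and_structure(self, learned_curves, config):
        tm = build_transition_model(learned_curves, k=1.0, config=config)
        assert np.allclose(tm.outcome_dist.sum(axis=2), 1.0, atol=1e-12)
        assert np.allclose(tm.outcome_dist[:, :, 2], 0.25)
        assert tm.p_cues == pytest.approx(1 / 6)
        assert tm.hazard(4) == pytest.approx(1 / 3)

    def test_first_observation_is_uninformed_prior(self, learned_curves, config):
        tm = build_transition_model(learned_curves, k=1.0, config=config)
        assert np.allclose(tm.outcome_dist[:, 0, :], [0.1875, 0.1875, 0.25, 0.1875, 0.1875])

    def test_non_stochastic_rows_rejected(self, learned_curves, config):
        from tokenmdp.mdp import TransitionModel

        bad = build_transition_model(learned_curves, k=1.0, config=config).outcome_dist
        bad = bad.copy()
        bad[0, 0, 0] += 0.1
        with pytest.raises(ValueError):
            TransitionModel(config=config, outcome_dist=bad)


class TestValueIteration:
    def test_zero_reward_gives_zero_values(self, learned_curves, config):
        tm = build_transition_model(learned_curves, k=1.0, config=config)
        K, S, E, N = 13, 6, 10, 18
        table, _ = value_iteration(tm, gamma=0.9, reward=np.zeros((K, S, E, N)))
        assert np.allclose(table.u, 0.0)

    def test_gamma_zero_keeps_only_immediate_reward(self, learned_curves, config):
        tm = build_transition_model(learned_curves, k=1.0, config=config)
        table, _ = value_iteration(tm, gamma=0.0)
        assert table.value(5, 4, 9, 10) == 5.0  # cash-out with five tokens
        assert table.value(5, 4, 1, 10) == 0.0
        assert table.value(0, 1, 9, 1) == 0.0

    def test_two_state_cycle_closed_form(self):
        """Deterministic cycle A -> B -> A with r(A)=1, gamma=0.5 has the
        exact fixed point u(A) = 4/3, u(B) = 2/3."""
        P = np.array([[[0.0, 1.0], [1.0, 0.0]]])
        u = value_iteration_dense(P, np.array([1.0, 0.0]), gamma=0.5)
        assert u[0] == pytest.approx(4 / 3, abs=1e-12)
        assert u[1] == pytest.approx(2 / 3, abs=1e-12)

    def test_dense_solver_rejects_non_stochastic_rows(self):
        with pytest.raises(ValueError):
            value_iteration_dense(np.array([[0.5, 0.4], [0, 1]]), np.zeros(2), 0.9)

    def test_mini_task_matches_independent_enumeration(self):
        """The structured solver and a brute-force dense solver on the
        explicitly enumerated miniature task agree at machine precision,
        both at a finite sweep count and at convergence."""
        tm = build_transition_model(mini_curves(), k=1.0, config=MINI)
        P, r = mini_dense_mdp(tm)
        for sweeps, tol in ((30, 0.0), (5000, 1e-13)):
            table, _ = value_iteration(tm, gamma=0.9, sweeps=sweeps, tol=tol or 1e-300)
            u_dense = np.zeros(P.shape[1])
            for _ in range(sweeps):
                new = r + 0.9 * (P @ u_dense).max(axis=0)
                if tol and np.max(np.abs(new - u_dense)) < tol:
                    u_dense = new
                    break
                u_dense = new
            assert np.abs(table.u.reshape(-1) - u_dense).max() < 1e-9

    def test_invalid_arguments_rejected(self, learned_curves, config):
        tm = build_transition_model(learned_curves, k=1.0, config=config)
        with pytest.raises(ValueError):
            value_iteration(tm, gamma=1.5)
        with pytest.raises(ValueError):
            value_iteration(tm, gamma=0.9, sweeps=0)


class TestChoiceProbabilities:
    def test_softmax_basics(self):
        assert np.allclose(mdp_choice_prob((1.3, 1.3), 5.0), [0.5, 0.5])
        assert np.allclose(mdp_choice_prob((9.0, 1.0), 0.0), [0.5, 0.5])

    def test_equal_action_values_at_first_observation(self, solved):
        """Before any outcome has been seen the two options are
        indistinguishable, so both actions carry the same value."""
        _, policy = solved
        q = policy.q
        assert np.abs(q[:, 0, :, :, 0] - q[:, 1, :, :, 0]).max() == 0.0

    def test_better_cue_preferred_after_learning(self, solved, config):
        """By the final observation the higher-delta option has the larger
        action value in every gain-containing condition."""
        from tokenmdp.calibration import better_action

        _, policy = solved
        for c in range(1, 6):  # conditions 1-5 contain a gain cue
            a_best = better_action(c, config)
            q = policy.q[c - 1, :, :, :, -1]
            p = mdp_choice_prob((q[a_best].mean(), q[1 - a_best].mean()), 2.0)
            assert p[0] > 0.5
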