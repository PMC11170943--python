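"""Motivation regressions, marginalization, and group statistics."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from tokenmdp.mdp import ValueTable
from tokenmdp.simulate import BehaviorGroundTruth, simulate_session
from tokenmdp.stats import (
    compare_correlations,
    fit_abort_logistic,
    fit_choice_rt,
    fit_fixation_rt,
    group_tests,
    kernel_smooth,
    marginalize_values,
    multivariate_feature_regressions,
    tukey_filter,
)


class TestTukeyFilter:
    def test_clean_data_unchanged(self):
        data = [0.2, 0.21, 0.22, 0.23]
        assert list(tukey_filter(data)) == data

    def test_upper_outlier_removed(self):
        # quartiles of (0.2 .. 0.23, 5.0): q75 + 1.5 IQR excludes only 5.0
        out = tukey_filter([0.2, 0.21, 0.22, 0.23, 5.0])
        assert 5.0 not in out and len(out) == 4

    def test_two_sided(self):
        data = [-10.0] + [1.0, 1.1, 1.2, 1.3, 1.4, 1.5] + [12.0]
        out = tukey_filter(data)
        assert -10.0 not in out and 12.0 not in out

    def test_short_input_passthrough_with_warning(self):
        with pytest.warns(UserWarning):
            out = tukey_filter([1.0, 2.0])
        assert list(out) == [1.0, 2.0]


class TestValueRegressions:
    def test_affine_invariance_of_sign_and_scale(self, config, ref_table, truth):
        """Rescaling the value table u -> a u + b leaves slope signs fixed
        and rescales slopes by exactly 1/a."""
        sess = simulate_session(config, truth, ref_table, n_blocks=6, seed=21)
        base = fit_fixation_rt(sess, ref_table)
        a, b = 3.0, -7.0
        rescaled = ValueTable(
            u=a * ref_table.u + b,
            config=ref_table.config,
            gamma=ref_table.gamma,
            sweeps_run=ref_table.sweeps_run,
            converged=ref_table.converged,
        )
        res = fit_fixation_rt(sess, rescaled)
        assert res.params["v_fix"] == pytest.approx(base.params["v_fix"] / a)
        resa = fit_abort_logistic(sess, rescaled)
        basea = fit_abort_logistic(sess, ref_table)
        assert resa.params["v_cue"] == pytest.approx(basea.params["v_cue"] / a, rel=1e-5)

    def test_constant_regressor_rejected(self, config, ref_table, truth):
        sess = simulate_session(config, truth, ref_table, n_blocks=2, seed=22)
        flat = ValueTable(
            u=np.full_like(ref_table.u, 2.0),
            config=ref_table.config,
            gamma=ref_table.gamma,
            sweeps_run=1,
            converged=True,
        )
        with pytest.raises(ValueError):
            fit_fixation_rt(sess, flat)
        with pytest.raises(ValueError):
            fit_choice_rt(sess, flat)  # dV identically zero

    def test_zero_aborts_rejected(self, config, ref_table):
        truth = BehaviorGroundTruth(abort_coefs=(-30.0, 0.0), seed=23)
        sess = simulate_session(config, truth, ref_table, n_blocks=2)
        with pytest.raises(ValueError):
            fit_abort_logistic(sess, ref_table)


class TestMarginalization:
    def test_toy_mean_and_constant_table(self, config, ref_table):
        cfg = ref_table.config
        u = np.zeros_like(ref_table.u)
        u[0, 3, 0, 11], u[1, 3, 0, 11], u[2, 3, 0, 11] = 1.0, 2.0, 3.0
        toy = ValueTable(u=u, config=cfg, gamma=0.9, sweeps_run=1, converged=True)
        marg = marginalize_values(toy, "NTk")
        # TSCO = 4 averages NTk = 0..8 (feasibility bound), here (1+2+3)/9
        assert marg.u[5, 3, 0, 11] == pytest.approx(6.0 / 9.0)
        const = ValueTable(
            u=np.full_like(u, 4.2), config=cfg, gamma=0.9, sweeps_run=1, converged=True
        )
        for feat in ("NTk", "TSCO", "NObs", "TE"):
            assert np.allclose(marginalize_values(const, feat).u, 4.2)

    def test_unknown_feature_rejected(self, ref_table):
        with pytest.raises(ValueError):
            marginalize_values(ref_table, "JUICE")

    def test_token_marginalization_attenuates_fixation_slope(
        self, config, ref_table, truth
    ):
        """Removing the dominant value-driving feature (token count) from
        the state value weakens the RT regression, mirroring the
        feature-contribution analysis."""
        sess = simulate_session(config, truth, ref_table, n_blocks=9, seed=24)
        full = fit_fixation_rt(sess, ref_table).params["v_fix"]
        marg = fit_fixation_rt(sess, marginalize_values(ref_table, "NTk")).params[
            "v_fix"
        ]
        assert abs(marg) < abs(full)


class TestMultivariate:
    def test_reference_level_contract_and_models(self, config, ref_table, truth):
        from tokenmdp.rw import RWParams

        sess = simulate_session(config, truth, ref_table, n_blocks=9, seed=25)
        res = multivariate_feature_regressions(
            sess, ref_table, rw_params=RWParams(alpha=truth.alpha, beta=truth.beta_rw)
        )
        ch = res["choice_rt_features"]
        assert "cond1" not in ch.params
        assert all(f"cond{c}" in ch.params for c in range(2, 7))
        assert set(res) == {
            "fix_rt_features",
            "choice_rt_features",
            "choice_rt_rw_chosen",
            "fixation_abort_features",
            "choice_abort_features",
        }
        # value-coupled RTs load on the token count, the dominant driver
        assert res["fix_rt_features"].params["ntk"] < 0
        assert res["choice_rt_rw_chosen"].params["rw_chosen"] < 0


class TestGroupStats:
    def test_coherent_sign_pattern_gives_exact_smallest_p(self):
        gs = group_tests(
            {f"m{i}": [-0.1 * (i + 1) - 0.01, -0.23] for i in range(5)},
            coef="b",
            direction="less",
        )
        assert gs.group_p == pytest.approx(1 / 32)
        assert all(d == 1 for d in gs.per_animal_dof.values())

    def test_null_distribution_enumeration(self):
        """Brute-force the n=5 signed-rank null over the 32 sign patterns:
        the attainable one-sided p values start at 1/32 and 2/32."""
        mags = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        pvals = set()
        for signs in itertools.product([-1, 1], repeat=5):
            res = sps.wilcoxon(mags * signs, alternative="less", method="exact")
            pvals.add(round(float(res.pvalue), 6))
        ordered = sorted(pvals)
        assert ordered[0] == pytest.approx(1 / 32)
        assert ordered[1] == pytest.approx(2 / 32)

    def test_single_animal_skips_group_test(self):
        gs = group_tests({"m1": [-0.1, -0.2, -0.3]}, coef="b")
        assert gs.group_p is None
        assert gs.per_animal_dof["m1"] == 2

    def test_too_few_sessions_rejected(self):
        with pytest.raises(ValueError):
            group_tests({"m1": [-0.1]})


class TestCorrelationComparison:
    def test_equal_correlations_give_p_one(self):
        assert compare_correlations(0.7, 0.7, 50) == pytest.approx(1.0)

    def test_monotone_in_difference(self):
        ps = [compare_correlations(0.5 + d, 0.5, 50) for d in (0.0, 0.1, 0.2, 0.3)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_closed_form(self):
        z = (np.arctanh(0.9) - np.arctanh(0.5)) / np.sqrt(2 / 47)
        expect = 2 * sps.norm.sf(abs(z))
        assert compare_correlations(0.9, 0.5, 50) == pytest.approx(expect)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_correlations(1.0, 0.5, 50)
        with pytest.raises(ValueError):
            compare_correlations(0.5, 0.2, 3)


class TestKernelSmooth:
    def test_constant_signal_preserved(self):
        grid, sm = kernel_smooth([0, 1, 2, 3], [2.0, 2.0, 2.0, 2.0])
        assert np.allclose(sm, 2.0)

    def test_single_point(self):
        grid, sm = kernel_smooth([1.5], [0.7])
        assert np.allclose(sm, 0.7)

    def test_two_point_gaussian_weighting(self):
        """At x = 0 the weight on the point at distance 1 is
        exp(-1 / (2 * 0.5^2)) relative to the local point."""
        grid, sm = kernel_smooth([0.0, 1.0], [0.0, 1.0], grid=[0.0], bandwidth=0.5)
        w = np.exp(-1 / (2 * 0.25))
        assert sm[0] == pytest.approx(w / (1 + w))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kernel_smooth([], [])
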