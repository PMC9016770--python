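import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import bd_grid_loglik, yule_loglik
from paleodiv.bd import (BDModelSpec, RateFunction, bd_loglik, fit_bd_family,
                         fit_results_table)
from paleodiv.env import make_env_interpolator
from paleodiv.simulate import SimulationConfig, simulate_bd_tree


class TestEnvCurve:
    def test_constant_samples(self):
        c = make_env_interpolator([(0, 5), (10, 5), (20, 5)])
        assert c(7.3) == pytest.approx(5.0)

    def test_clamping(self):
        c = make_env_interpolator([(0, 0), (10, 10)])
        assert c(25) == pytest.approx(10.0)
        assert c(-3) == pytest.approx(0.0)

    @given(st.floats(0.5, 9.5))
    @settings(max_examples=20, deadline=None)
    def test_linear_interpolation(self, x):
        c = make_env_interpolator([(0, 0), (10, 10)])
        assert c(x) == pytest.approx(x, abs=1e-9)

    def test_smoothing_df_recorded(self):
        ages = np.linspace(0, 25, 60)
        vals = np.sin(ages) + 0.1 * ages
        c = make_env_interpolator(np.column_stack([ages, vals]), smooth_df=12)
        assert c.smooth_df == 12
        c2 = make_env_interpolator(np.column_stack([ages, vals]))
        # exact-interpolation regime reproduces samples
        c3 = make_env_interpolator(np.column_stack([ages, vals]), smooth_df=60)
        np.testing.assert_allclose(c3(ages), vals, atol=1e-8)

    def test_errors(self):
        with pytest.raises(ValueError):
            make_env_interpolator([(0, 1)])
        with pytest.raises(ValueError):
            make_env_interpolator([(0, 1), (0, 2), (5, 3)])


class TestBDLoglik:
    def test_two_tip_analytic(self):
        """P(no further speciation on two lineages over T) = exp(-2 lam T)."""
        spec = BDModelSpec(RateFunction("constant", 0.1), None, 1.0, "none")
        assert bd_loglik(np.array([10.0]), spec) == pytest.approx(-2.0)

    def test_env_alpha_zero_equals_constant(self, bt4):
        env = make_env_interpolator([(0, 2), (5, 7), (10, 3), (25, 9)])
        s1 = BDModelSpec(RateFunction("exp_env", 0.2, 0.0, env),
                         RateFunction("constant", 0.05), 0.9)
        s2 = BDModelSpec(RateFunction("constant", 0.2),
                         RateFunction("constant", 0.05), 0.9)
        assert bd_loglik(bt4, s1) == bd_loglik(bt4, s2)

    def test_grid_oracle_constant(self, bt4):
        spec = BDModelSpec(RateFunction("constant", 0.3),
                           RateFunction("constant", 0.1), 0.9)
        oracle = bd_grid_loglik(bt4, lambda t: 0.3, lambda t: 0.1, 0.9)
        assert bd_loglik(bt4, spec) == pytest.approx(oracle, abs=1e-4)

    def test_grid_oracle_time_varying(self, bt4):
        spec = BDModelSpec(RateFunction("exp_time", 0.25, 0.15),
                           RateFunction("exp_time", 0.08, -0.1), 0.85)
        oracle = bd_grid_loglik(bt4, lambda t: 0.25 * np.exp(0.15 * t),
                                lambda t: 0.08 * np.exp(-0.1 * t), 0.85)
        assert bd_loglik(bt4, spec) == pytest.approx(oracle, abs=1e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_yule_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        bt = np.sort(rng.uniform(0.2, 14.0, rng.integers(3, 25)))[::-1]
        lam = rng.uniform(0.05, 0.5)
        spec = BDModelSpec(RateFunction("constant", lam), None, 1.0, "none")
        assert bd_loglik(bt, spec) == pytest.approx(yule_loglik(bt, lam),
                                                    abs=1e-8)

    def test_continuity_in_parameters(self, bt4):
        base = bd_loglik(bt4, BDModelSpec(RateFunction("exp_time", 0.2, 0.1),
                                          RateFunction("constant", 0.05), 0.9))
        for dl, da in ((1e-6, 0), (0, 1e-6)):
            near = bd_loglik(bt4, BDModelSpec(
                RateFunction("exp_time", 0.2 + dl, 0.1 + da),
                RateFunction("constant", 0.05), 0.9))
            assert abs(near - base) < 1e-3

    def test_negative_rate_rejected(self):
        from paleodiv.bd import LikelihoodError
        with pytest.raises(LikelihoodError):
            RateFunction("constant", -0.1)


class TestFitBDFamily:
    def test_aic_consistency_and_tables(self, bt4):
        res = fit_bd_family(bt4, "time", f=1.0, n_starts=1, seed=0)
        assert len(res) == 6
        for r in res:
            assert r.aic == pytest.approx(2 * r.n_params - 2 * r.loglik,
                                          abs=1e-9)
        table = fit_results_table(res)
        assert table["dAIC"].iloc[0] == 0.0
        assert table["wAIC"].sum() == pytest.approx(1.0)

    def test_env_constant_curve_collapses_to_time_family(self, bt4):
        env = make_env_interpolator([(0, 5), (10, 5), (25, 5)])
        env_res = fit_bd_family(bt4, "env", env=env, f=1.0, n_starts=1, seed=0)
        time_res = fit_bd_family(bt4, "time", f=1.0, n_starts=1, seed=0)
        best_env = max(r.loglik for r in env_res if r.label == "BENV")
        yule = next(r.loglik for r in time_res if r.label == "BCST")
        assert best_env == pytest.approx(yule, abs=1e-4)

    def test_yule_recovery(self):
        """Yule simulations: the pure-birth model wins and lambda is
        recovered; scaled-down version of the 200-tree experiment."""
        lam_true = 0.2
        spec = BDModelSpec(RateFunction("constant", lam_true), None, 1.0)
        wins, lams = 0, []
        for seed in range(10):
            t = simulate_bd_tree(spec, SimulationConfig(
                seed=seed, crown_age=25.0, conditioning="n_tips",
                target_tips=100, tip_tolerance=0.4, max_attempts=300))
            res = fit_bd_family(t.branching_times(), "time", f=1.0,
                                n_starts=1, seed=seed)
            ok = [r for r in res if r.converged]
            best = min(ok, key=lambda r: r.aic)
            wins += best.label == "BCST"
            lams.append(next(r.params["lambda0"] for r in ok
                             if r.label == "BCST"))
        assert wins >= 6
        assert abs(np.median(lams) - lam_true) / lam_true < 0.10
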