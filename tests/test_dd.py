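import numpy as np
import pytest

from oracles import dd_matexp_loglik
from paleodiv.bd import BDModelSpec, RateFunction, bd_loglik
from paleodiv.dd import DDModel, dd_loglik, fit_dd_family
from paleodiv.simulate import SimulationConfig, simulate_dd_tree

BT10 = np.array([3.0, 2.5, 2.1, 1.7, 1.2, 0.9, 0.5, 0.3, 0.2])


class TestDDLoglik:
    def test_large_K_equals_constant_rate(self):
        m = DDModel("DDL+E", lambda0=0.3, mu0=0.1, K=1e6, f=0.9)
        spec = BDModelSpec(RateFunction("constant", 0.3),
                           RateFunction("constant", 0.1), 0.9)
        assert dd_loglik(BT10, m) == pytest.approx(
            bd_loglik(BT10, spec), abs=1e-3)

    def test_overfull_clade_impossible(self):
        # 10 tips with K = 4: lambda clamps to 0 before the last branchings
        m = DDModel("DDL", lambda0=0.4, K=4.0, f=1.0, conditioning="none")
        assert dd_loglik(BT10, m) == -np.inf

    @pytest.mark.parametrize("model,M", [
        (DDModel("DDL", 0.5, K=6.0, f=0.85, conditioning="none"), 60),
        (DDModel("DDL+E", 0.5, 0.12, K=8.0, f=0.85, conditioning="none"), 80),
        (DDModel("DDX+E", 0.5, 0.15, x=0.4, f=0.85, conditioning="none"), 120),
        (DDModel("DD+EL", 0.35, 0.05, K=9.0, f=0.9, conditioning="none"), 80),
        (DDModel("DD+EX", 0.35, 0.05, x=0.5, f=0.9, conditioning="none"), 80),
    ])
    def test_matrix_exponential_oracle(self, bt4, model, M):
        assert dd_loglik(bt4, model) == pytest.approx(
            dd_matexp_loglik(bt4, model, M=M), abs=1e-4)

    def test_monotone_approach_to_constant_rate(self):
        spec = BDModelSpec(RateFunction("constant", 0.3),
                           RateFunction("constant", 0.05), 0.9)
        target = bd_loglik(BT10, spec)
        gaps = []
        for K in (1e2, 1e3, 1e4):
            m = DDModel("DDL+E", 0.3, 0.05, K=K, f=0.9)
            gaps.append(abs(dd_loglik(BT10, m) - target))
        assert gaps[0] > gaps[1] > gaps[2]

    def test_rate_clamping_nonnegative(self):
        m = DDModel("DDL", 0.3, K=5.0, f=1.0)
        assert np.all(m.lam(np.arange(0, 50)) >= 0)
        m2 = DDModel("DDL+E", 0.3, 0.1, K=5.0, f=1.0)
        assert np.all(m2.lam(np.arange(0, 50)) >= 0)

    def test_pure_birth_fast_path_matches_master_equation(self, bt4):
        m = DDModel("DDL", 0.4, K=12.0, f=1.0, conditioning="none")
        assert dd_loglik(bt4, m) == pytest.approx(
            dd_matexp_loglik(bt4, m, M=40), abs=1e-8)

    def test_ddl_forces_zero_extinction(self):
        m = DDModel("DDL", 0.3, mu0=0.5, K=10.0)
        assert m.mu0 == 0.0


class TestFitDDFamily:
    def test_known_species_validation(self):
        with pytest.raises(ValueError):
            fit_dd_family(BT10, f=1.0, known_species=5)

    def test_ddl_recovery_small(self):
        """DDL simulated trees: K and lambda0 roughly recovered (a small
        pilot; the full 50-replicate experiment runs in the acceptance
        suite)."""
        errs = []
        for seed in range(6):
            m = DDModel("DDL", 0.3, K=70.0, f=1.0)
            t = simulate_dd_tree(m, SimulationConfig(seed=seed,
                                                     crown_age=17.5, f=1.0))
            r = fit_dd_family(t.branching_times(), f=1.0, variants=("DDL",),
                              seed=seed)[0]
            errs.append(abs(r.params["K"] - 70.0) / 70.0)
        assert np.median(errs) < 0.25

    def test_yule_specificity(self):
        """Trees grown without diversity dependence should not prefer DDL
        over the Yule model by AIC in most replicates."""
        from paleodiv.simulate import simulate_bd_tree

        spec = BDModelSpec(RateFunction("constant", 0.2), None, 1.0)
        prefer_dd = 0
        n = 8
        for seed in range(n):
            t = simulate_bd_tree(spec, SimulationConfig(
                seed=seed + 40, crown_age=17.5, conditioning="n_tips",
                target_tips=60, tip_tolerance=0.4, max_attempts=300))
            bt = t.branching_times()
            ddl = fit_dd_family(bt, f=1.0, variants=("DDL",), seed=seed)[0]
            yule = BDModelSpec(RateFunction("constant",
                                            np.log(t.n_tips / 2) / bt[0]),
                               None, 1.0)
            from scipy.optimize import minimize_scalar
            res = minimize_scalar(
                lambda l: -bd_loglik(bt, BDModelSpec(
                    RateFunction("constant", l), None, 1.0)),
                bounds=(1e-4, 2.0), method="bounded")
            aic_yule = 2 * 1 + 2 * res.fun
            prefer_dd += ddl.aic < aic_yule
        assert prefer_dd <= n // 2
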