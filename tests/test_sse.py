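import numpy as np
import pytest

from oracles import sse_grid_loglik
from paleodiv.bd import BDModelSpec, RateFunction, bd_loglik
from paleodiv.phylo import parse_newick
from paleodiv.sse import (SSEModelSpec, STRUCTURES, enumerate_model_space,
                          fit_sse, node_state_probs, sse_loglik)


class TestModelSpace:
    def test_exactly_36_unique_models(self):
        space = enumerate_model_space()
        assert len(space) == 36
        assert len({s.label for s in space}) == 36

    def test_examined_transition_parameter_counts(self):
        expected = {"Unconstrained1": 1, "Unconstrained6": 6,
                    "Constrained1": 1, "Constrained4": 4,
                    "ConstrainedSpecialist": 2, "ConstrainedOpenness": 2}
        for s in enumerate_model_space():
            assert s.n_exam_trans == expected[s.structure]

    def test_cr_dual_parameter_bookkeeping(self):
        s = SSEModelSpec("CR", "dual", "Unconstrained1", d=3)
        # lambda + mu + 1 examined transition + 1 concealed rate
        assert s.n_params == 4

    def test_constrained_structures_forbid_forest_open(self):
        for st in ("Constrained1", "Constrained4", "ConstrainedSpecialist",
                   "ConstrainedOpenness"):
            spec = SSEModelSpec("CR", "dual", st, d=1).with_params(
                np.concatenate([[0.2, 0.01],
                                np.full(SSEModelSpec("CR", "dual", st,
                                                     d=1).n_exam_trans, 0.1)]))
            Q = spec.q_matrix()
            assert Q[0, 2] == 0 and Q[2, 0] == 0

    def test_clado_rates_conserve_lambda(self):
        for dep in ("ETD", "CR"):
            for inh in ("dual", "single"):
                for st in STRUCTURES:
                    spec = SSEModelSpec(dep, inh, st, d=2)
                    theta = np.abs(np.sin(np.arange(1, spec.n_params + 1)))
                    spec = spec.with_params(theta)
                    cpar, ca, cb, crate = spec.clado_events()
                    lam = spec.lambda_by_state()
                    tot = np.zeros(spec.n_states)
                    np.add.at(tot, cpar, crate)
                    np.testing.assert_allclose(tot, lam, atol=1e-12)


class TestSSELoglik:
    def test_cr_reduces_to_trait_free_bd(self, tree5):
        tips = {k: 1 for k in "ABCDE"}
        spec = SSEModelSpec("CR", "dual", "Unconstrained1", d=3,
                            f=0.9).with_params([0.3, 0.1, 0.0, 0.0])
        ll = sse_loglik(tree5, tips, spec, rtol=1e-11, atol=1e-13)
        bd_spec = BDModelSpec(RateFunction("constant", 0.3),
                              RateFunction("constant", 0.1), 0.9)
        target = bd_loglik(tree5.branching_times(), bd_spec,
                           rtol=1e-11, atol=1e-13)
        assert ll == pytest.approx(target, abs=1e-8)

    def test_grid_oracle_dual_d1(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        tips = {"A": 0, "B": 2, "C": 1}
        spec = SSEModelSpec("ETD", "dual", "Unconstrained6", d=1,
                            f=0.85).with_params(
            [0.25, 0.4, 0.1, 0.06, 0.11, 0.04, 0.09, 0.13, 0.05, 0.08])
        assert sse_loglik(tree, tips, spec, rtol=1e-10, atol=1e-12) == \
            pytest.approx(sse_grid_loglik(tree, tips, spec), abs=1e-4)

    def test_grid_oracle_single_inheritance(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        tips = {"A": 0, "B": 2, "C": 1}
        spec = SSEModelSpec("ETD", "single", "Constrained4", d=1,
                            f=0.9).with_params(
            [0.25, 0.4, 0.1, 1e-6, 0.05, 0.08, 0.06, 0.03])
        assert sse_loglik(tree, tips, spec, rtol=1e-10, atol=1e-12) == \
            pytest.approx(sse_grid_loglik(tree, tips, spec), abs=1e-4)

    def test_single_inheritance_alternative_symmetry(self, tree5, tips5):
        """Permuting the two non-parental habitats (with the data) leaves the
        likelihood unchanged under a symmetric structure."""
        spec = SSEModelSpec("CR", "single", "Unconstrained1", d=2,
                            f=0.9).with_params([0.3, 0.05, 0.1, 0.07])
        perm = {0: 2, 1: 1, 2: 0}
        ll1 = sse_loglik(tree5, tips5, spec)
        ll2 = sse_loglik(tree5, {k: perm[v] for k, v in tips5.items()}, spec)
        assert ll1 == pytest.approx(ll2, abs=1e-10)

    def test_concealed_label_permutation_invariance(self, tree5, tips5):
        """CTD lambdas permuted across concealed states give the same
        likelihood (concealed labels are arbitrary)."""
        base = SSEModelSpec("CTD", "dual", "Unconstrained1", d=3, f=0.9)
        ll1 = sse_loglik(tree5, tips5,
                         base.with_params([0.1, 0.3, 0.2, 0.02, 0.05, 0.04]))
        ll2 = sse_loglik(tree5, tips5,
                         base.with_params([0.3, 0.2, 0.1, 0.02, 0.05, 0.04]))
        assert ll1 == pytest.approx(ll2, abs=1e-9)


class TestNodeStateProbs:
    def test_zero_transitions_monomorphic(self, tree5):
        tips = {k: 0 for k in "ABCDE"}
        spec = SSEModelSpec("CR", "dual", "Unconstrained1", d=2,
                            f=0.9).with_params([0.3, 0.01, 0.0, 0.0])
        probs = node_state_probs(tree5, tips, spec)
        np.testing.assert_allclose(probs[:, 0], 1.0, atol=1e-9)

    def test_symmetric_two_tip_root(self):
        tree = parse_newick("(A:2,B:2);")
        spec = SSEModelSpec("CR", "dual", "Unconstrained1", d=1,
                            f=1.0, conditioning=False).with_params(
            [0.2, 0.01, 0.08])
        probs = node_state_probs(tree, {"A": 0, "B": 2}, spec)
        assert probs[0, 0] == pytest.approx(probs[0, 2], abs=1e-9)

    def test_against_restricted_likelihood_oracle(self, tree5, tips5):
        """Marginal at a node == renormalized likelihoods with that node
        clamped to each habitat state."""
        spec = SSEModelSpec("ETD", "dual", "Unconstrained1", d=2, f=0.9,
                            conditioning=False,
                            root_weighting="uniform").with_params(
            [0.25, 0.4, 0.1, 0.05, 0.08, 0.06])
        probs = node_state_probs(tree5, tips5, spec, rtol=1e-10, atol=1e-12)
        for row, node in zip(probs, tree5.internal_nodes()):
            lls = np.array([
                sse_loglik(tree5, tips5, spec, rtol=1e-10, atol=1e-12,
                           _clamp=(id(node), s)) for s in range(3)])
            w = np.exp(lls - lls.max())
            np.testing.assert_allclose(row, w / w.sum(), atol=1e-8)


class TestFitSSE:
    def test_fit_smoke_and_aicc(self, tree5, tips5):
        spec = SSEModelSpec("CR", "dual", "Unconstrained1", d=1, f=1.0)
        res = fit_sse(tree5, tips5, spec, n_starts=1, seed=0)
        assert res.converged
        assert res.aicc(5) > res.aic
        assert np.isfinite(res.loglik)


class TestValidateBySimulation:
    def test_easy_regime_confusion_table(self):
        """Strongly distinct ETD vs CTD generating models on moderate trees:
        the confusion table is well formed and mostly diagonal."""
        from paleodiv.sse import validate_by_simulation

        etd = SSEModelSpec("ETD", "dual", "Unconstrained1", d=2,
                           f=1.0).with_params([0.5, 0.05, 0.05, 1e-6, 0.1, 0.05])
        ctd = SSEModelSpec("CTD", "dual", "Unconstrained1", d=2,
                           f=1.0).with_params([0.5, 0.05, 1e-6, 0.1, 0.05])
        conf = validate_by_simulation(etd, ctd, target_tips=50, n_sims=2,
                                      seed=1, n_starts=1, fit_d=2)
        assert conf.values.sum() == 4
        assert (conf.values >= 0).all()
        # the generating model should win more often than it loses
        assert conf.values[0, 0] + conf.values[1, 1] >= 3
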