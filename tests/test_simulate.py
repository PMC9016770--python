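import json

import numpy as np
import pytest

from paleodiv.bd import BDModelSpec, RateFunction
from paleodiv.dd import DDModel
from paleodiv.episodic import EpisodicModel
from paleodiv.simulate import (SimulationConfig, SimulationError,
                               make_fixture_study, simulate_bd_tree,
                               simulate_dd_tree, simulate_episodic_tree,
                               simulate_sse_tree, synthetic_env_curve,
                               write_fixture)
from paleodiv.sse import SSEModelSpec


class TestBDSimulator:
    def test_seed_determinism(self):
        spec = BDModelSpec(RateFunction("constant", 0.2), None, 1.0)
        cfg = SimulationConfig(seed=5, crown_age=10.0)
        assert simulate_bd_tree(spec, cfg).write_newick() == \
            simulate_bd_tree(spec, cfg).write_newick()

    def test_crown_conditioned_pure_birth_mean_tips(self):
        """E[tips | crown survival, mu=0] = 2 e^(lam T)."""
        lam, T = 0.2, 10.0
        spec = BDModelSpec(RateFunction("constant", lam), None, 1.0)
        counts = [simulate_bd_tree(spec, SimulationConfig(seed=i,
                                                          crown_age=T)).n_tips
                  for i in range(150)]
        expect = 2 * np.exp(lam * T)
        assert abs(np.mean(counts) - expect) < 3 * np.std(counts) / np.sqrt(150)

    def test_no_pruning_when_complete(self):
        """mu=0, f=1: every simulated speciation appears in the tree."""
        spec = BDModelSpec(RateFunction("constant", 0.3), None, 1.0)
        from paleodiv.simulate import _run_conditioned
        cfg = SimulationConfig(seed=7, crown_age=8.0)

        def rate_cb(age, states):
            n = len(states)
            return np.full(n, 0.3), np.zeros(n), None

        tree, _, log = _run_conditioned(cfg, rate_cb, lambda rng: (0, 0),
                                        lambda st, rng: (st, st))
        n_spec = sum(1 for e in log if e[0] == "speciation")
        assert tree.n_tips == n_spec + 2

    def test_attempt_cap_error(self):
        spec = BDModelSpec(RateFunction("constant", 0.01),
                           RateFunction("constant", 2.0), 1.0)
        with pytest.raises(SimulationError, match="cap"):
            simulate_bd_tree(spec, SimulationConfig(seed=0, crown_age=20.0,
                                                    max_attempts=5))

    def test_ultrametric_after_pruning(self):
        spec = BDModelSpec(RateFunction("constant", 0.35),
                           RateFunction("constant", 0.15), 0.7)
        t = simulate_bd_tree(spec, SimulationConfig(seed=3, crown_age=12.0,
                                                    f=0.7))
        ages = [tip.age for tip in t.tips()]
        assert np.allclose(ages, 0.0, atol=1e-9)


class TestEpisodicAndDDSimulators:
    def test_zero_rate_recent_epoch(self):
        """A second epoch with (near) zero speciation leaves no branchings
        younger than the shift."""
        m = EpisodicModel([4.0], [1e-6, 0.4], [0.0, 0.0], f=1.0)
        t = simulate_episodic_tree(m, SimulationConfig(seed=1, crown_age=12.0))
        assert t.branching_times().min() >= 4.0 - 1e-9

    def test_ddl_equilibrates_near_K(self):
        K = 40.0
        counts = [simulate_dd_tree(
            DDModel("DDL", 0.5, K=K, f=1.0, conditioning="none"),
            SimulationConfig(seed=i, crown_age=40.0)).n_tips
            for i in range(15)]
        assert abs(np.mean(counts) - K) < 5

    def test_episodic_degenerate_matches_constant(self):
        """Identical rates in both epochs: same tip-count distribution as
        the constant simulator (same seeds give close means)."""
        m = EpisodicModel([5.0], [0.15, 0.15], [0.2, 0.2], f=1.0)
        spec = BDModelSpec(RateFunction("constant", 0.15 / 0.8),
                           RateFunction("constant", 0.15 / 0.8 * 0.2), 1.0)
        a = [simulate_episodic_tree(m, SimulationConfig(seed=i,
                                                        crown_age=10.0)).n_tips
             for i in range(120)]
        b = [simulate_bd_tree(spec, SimulationConfig(seed=10_000 + i,
                                                     crown_age=10.0)).n_tips
             for i in range(120)]
        from scipy.stats import ks_2samp
        assert ks_2samp(a, b).pvalue > 0.01


class TestSSESimulator:
    def test_zero_transitions_monomorphic(self):
        spec = SSEModelSpec("CR", "dual", "Unconstrained1", d=1,
                            f=1.0).with_params([0.3, 0.0, 0.0])
        tree, tips = simulate_sse_tree(spec, SimulationConfig(seed=2,
                                                              crown_age=8.0))
        assert len(set(tips.values())) == 1

    def test_single_inheritance_keeps_parent_state(self):
        spec = SSEModelSpec("CR", "single", "Unconstrained1", d=1,
                            f=1.0).with_params([0.4, 0.0, 0.02])
        _, _, log = simulate_sse_tree(
            spec, SimulationConfig(seed=4, crown_age=8.0), return_log=True)
        forks = [e for e in log if e[0] == "speciation"]
        assert forks
        for _, _, parent, daughters in forks:
            assert parent in daughters
            assert any(d != parent for d in daughters)

    def test_stationary_state_frequencies(self):
        """Fast symmetric habitat switching pushes tip states toward the
        uniform stationary distribution."""
        spec = SSEModelSpec("CR", "dual", "Unconstrained1", d=1,
                            f=1.0).with_params([0.25, 0.0, 1.5])
        freqs = np.zeros(3)
        for seed in range(10):
            _, tips = simulate_sse_tree(spec, SimulationConfig(
                seed=seed, crown_age=15.0, conditioning="n_tips",
                target_tips=60, tip_tolerance=0.5, max_attempts=200))
            for s in tips.values():
                freqs[s] += 1
        freqs /= freqs.sum()
        assert np.abs(freqs - 1 / 3).max() < 0.12


class TestEnvCurves:
    def test_constant_flat(self):
        c = synthetic_env_curve("constant", seed=0)
        ages = np.linspace(0, 25, 40)
        assert np.ptp(c(ages)) < 1e-9

    def test_cooling_trend_monotone(self):
        c = synthetic_env_curve("cooling_trend", seed=1)
        ages = np.linspace(0, 25, 200)
        assert np.all(np.diff(c(ages)) > 0)

    def test_oscillation_period_by_fft(self):
        c = synthetic_env_curve("oscillation", seed=2)
        ages = np.linspace(0, 25, 512)
        v = c(ages) - np.mean(c(ages))
        freqs = np.fft.rfftfreq(ages.size, d=ages[1] - ages[0])
        peak = freqs[np.argmax(np.abs(np.fft.rfft(v))[1:]) + 1]
        assert 1 / peak == pytest.approx(5.0, rel=0.1)


class TestStudyFixture:
    @pytest.fixture(scope="class")
    def fixture(self):
        return make_fixture_study(seed=0)

    def test_shape(self, fixture):
        assert 80 <= fixture.tree.n_tips <= 110
        assert 15.0 <= fixture.tree.crown_age <= 25.0

    def test_clades_partition_tips(self, fixture):
        a = set(fixture.clades["Clade_I"])
        b = set(fixture.clades["Clade_II"])
        assert a.isdisjoint(b)
        assert a | b == set(fixture.tree.tip_labels)

    def test_all_three_habitats_present(self, fixture):
        assert set(fixture.habitats.values()) == {0, 1, 2}

    def test_bundle_round_trip(self, fixture, tmp_path):
        from paleodiv.env import read_env_csv
        from paleodiv.mk import read_trait_tsv
        from paleodiv.phylo import parse_newick

        write_fixture(fixture, tmp_path)
        tree = parse_newick((tmp_path / "tree.nwk").read_text())
        assert tree.n_tips == fixture.tree.n_tips
        traits = read_trait_tsv(tmp_path / "habitats.tsv", tree)
        assert traits == fixture.habitats
        env = read_env_csv(tmp_path / "env_temperature.csv")
        assert env.age_range[1] == pytest.approx(25.0)
        clades = json.loads((tmp_path / "clades.json").read_text())
        assert set(clades) == {"Clade_I", "Clade_II"}
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["seed"] == 0
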