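"""Forward-time simulators for every model class, plus the study-shaped
synthetic fixture that stands in for the deposited empirical data.

All simulators run a Gillespie process on the complete tree (with per-lineage
habitat states for SSE models), then prune extinct lineages and unsampled
tips (i.i.d. Bernoulli retention with probability f) to the reconstructed
ultrametric tree. Conditioning (crown survival, or a target reconstructed
tip count) is enforced by resimulation with a bounded attempt budget, never
by silently altering the requested parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bd import BDModelSpec
from .dd import DDModel
from .env import EnvCurve, make_env_interpolator
from .episodic import EpisodicModel, rates_from_rt
from .mk import STATES
from .phylo import Node, Phylogeny
from .sse import SSEModelSpec, _ADJACENCY, N_EXAM

__all__ = [
    "SimulationConfig", "SimulationError",
    "simulate_bd_tree", "simulate_episodic_tree", "simulate_dd_tree",
    "simulate_sse_tree", "synthetic_env_curve",
    "make_fixture_study", "write_fixture", "StudyFixture",
]


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    seed: int
    crown_age: float
    f: float = 1.0
    conditioning: str = "crown_survival"   # crown_survival | n_tips | none
    target_tips: int | None = None
    tip_tolerance: float = 0.1             # fractional band for n_tips mode
    max_attempts: int = 1000

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.max_attempts <= 0:
            raise ValueError("attempt cap must be positive")
        if self.conditioning == "n_tips" and not self.target_tips:
            raise ValueError("n_tips conditioning requires target_tips")


# -- core Gillespie over the complete process --------------------------------


class _Lineage:
    __slots__ = ("node", "start", "state")

    def __init__(self, node, start, state):
        self.node = node
        self.start = start
        self.state = state


def _gillespie(T, rng, rate_cb, init_states, window=0.25):
    """Forward simulation on [0, T] (age = T - s).

    rate_cb(age, states) -> (lam_per_lineage, mu_per_lineage, trans_matrix)
    where trans_matrix[i] gives per-lineage anagenetic transition rates to
    each target state (or None for state-free models). Time-varying rates
    are handled by thinning against a bound taken over a short window.
    Returns (root Node, list of surviving _Lineage, event log).
    """
    root = Node(label=None, length=0.0)
    c1 = Node(parent=root)
    c2 = Node(parent=root)
    root.children = [c1, c2]
    s0, s1 = init_states
    active = [_Lineage(c1, 0.0, s0), _Lineage(c2, 0.0, s1)]
    log = []
    s = 0.0
    while s < T and active:
        states = [ln.state for ln in active]
        w_end = min(s + window, T)
        tot_now = _total_rate(rate_cb, T - s, states)
        tot_end = _total_rate(rate_cb, T - w_end, states)
        bound = 1.05 * max(tot_now, tot_end, 1e-12)
        dt = rng.exponential(1.0 / bound)
        if s + dt > w_end:
            s = w_end
            continue
        s += dt
        lam, mu, trans = rate_cb(T - s, states)
        rates = np.concatenate([
            lam, mu, trans.ravel() if trans is not None else np.empty(0)])
        tot = rates.sum()
        if rng.random() > tot / bound:      # thinning rejection
            continue
        idx = rng.choice(rates.size, p=rates / tot)
        n = len(active)
        if idx < n:                          # speciation
            ln = active[idx]
            ln.node.length = s - ln.start
            d1 = Node(parent=ln.node)
            d2 = Node(parent=ln.node)
            ln.node.children = [d1, d2]
            st1, st2 = yield_states = _CLADO_CB[0](ln.state, rng)
            log.append(("speciation", s, ln.state, yield_states))
            active[idx] = _Lineage(d1, s, st1)
            active.append(_Lineage(d2, s, st2))
        elif idx < 2 * n:                    # extinction
            ln = active[idx - n]
            ln.node.length = s - ln.start
            log.append(("extinction", s, ln.state, None))
            active.pop(idx - n)
        else:                                # anagenetic state change
            k = idx - 2 * n
            li, target = divmod(k, trans.shape[1])
            ln = active[li]
            log.append(("transition", s, ln.state, target))
            ln.state = int(target)
    for ln in active:
        ln.node.length = T - ln.start
        ln.node.age = 0.0
    return root, active, log


_CLADO_CB = [None]   # set per call: state -> (daughter_state_1, daughter_state_2)


def _total_rate(rate_cb, age, states):
    lam, mu, trans = rate_cb(age, states)
    tot = lam.sum() + mu.sum()
    if trans is not None:
        tot += trans.sum()
    return tot


def _prune_reconstructed(root, survivors, rng, f, per_state_f=None):
    """Bernoulli tip sampling then pruning to the reconstructed tree.

    Returns (Phylogeny or None, kept crown sides (bool, bool), tip states).
    """
    sampled = {}
    for ln in survivors:
        p = f if per_state_f is None else per_state_f[ln.state]
        if rng.random() < p:
            sampled[id(ln.node)] = ln.state

    def prune(node):
        if not node.children:
            if id(node) in sampled:
                return node, sampled[id(node)]
            return None, None
        kept = []
        states = {}
        for ch in node.children:
            sub, st = prune(ch)
            if sub is not None:
                kept.append(sub)
                if isinstance(st, dict):
                    states.update(st)
                else:
                    states[id(sub)] = st
        if not kept:
            return None, None
        if len(kept) == 1:
            child = kept[0]
            child.length += node.length
            return child, states
        node.children = kept
        for ch in kept:
            ch.parent = node
        return node, states

    sides = []
    new_children = []
    all_states = {}
    for ch in root.children:
        sub, st = prune(ch)
        sides.append(sub is not None)
        if sub is not None:
            new_children.append(sub)
            if isinstance(st, dict):
                all_states.update(st)
            else:
                all_states[id(sub)] = st
    if len(new_children) < 2:
        return None, tuple(sides), {}
    root.children = new_children
    for ch in new_children:
        ch.parent = root
    return root, tuple(sides), all_states


def _label_tips(root, prefix="t"):
    i = 0
    stack = [root]
    order = {}
    while stack:
        node = stack.pop()
        if not node.children:
            i += 1
            node.label = f"{prefix}{i}"
            order[id(node)] = node.label
        else:
            stack.extend(reversed(node.children))
    return order


def _run_conditioned(config: SimulationConfig, build_rate_cb, init_state_fn,
                     clado_fn, per_state_f=None, want_states=False,
                     prefix="t"):
    rng = np.random.default_rng(config.seed)
    T = config.crown_age
    last_fail = "no attempt"
    for attempt in range(config.max_attempts):
        _CLADO_CB[0] = clado_fn
        root, survivors, log = _gillespie(T, rng, build_rate_cb,
                                          init_state_fn(rng))
        if not survivors:
            last_fail = "clade extinct"
            continue
        pruned, sides, id_states = _prune_reconstructed(
            root, survivors, rng, config.f, per_state_f)
        if pruned is None:
            last_fail = f"crown side lost (sides kept: {sides})"
            continue
        if config.conditioning == "crown_survival" and not all(sides):
            last_fail = "one crown lineage left no sampled descendant"
            continue
        n_tips = sum(1 for _ in _iter_tips(pruned))
        if config.conditioning == "n_tips":
            lo = config.target_tips * (1 - config.tip_tolerance)
            hi = config.target_tips * (1 + config.tip_tolerance)
            if not (lo <= n_tips <= hi):
                last_fail = f"tip count {n_tips} outside [{lo:.0f}, {hi:.0f}]"
                continue
        labels = _label_tips(pruned, prefix)
        pruned.length = 0.0
        pruned.parent = None
        tree = Phylogeny(pruned)
        if want_states:
            tip_states = {labels[i]: int(s) for i, s in id_states.items()}
            return tree, tip_states, log
        return tree, None, log
    raise SimulationError(
        f"attempt cap {config.max_attempts} exceeded; last failure: "
        f"{last_fail} (survival appears rare under these parameters)")


def _iter_tips(node):
    stack = [node]
    while stack:
        n = stack.pop()
        if not n.children:
            yield n
        else:
            stack.extend(n.children)


# -- public simulators -------------------------------------------------------


def simulate_bd_tree(spec: BDModelSpec, config: SimulationConfig) -> Phylogeny:
    """Reconstructed tree under a (possibly time/env-dependent) BD model."""
    lam_fn, mu_fn = spec.lambda_fn, spec.mu

    def rate_cb(age, states):
        n = len(states)
        lam = np.full(n, float(lam_fn(age)))
        mu = np.full(n, float(mu_fn(age)))
        return lam, mu, None

    cfg = config
    if cfg.f == 1.0 and spec.sampling_fraction != 1.0:
        cfg = SimulationConfig(**{**asdict(config), "f": spec.sampling_fraction})
    tree, _, _ = _run_conditioned(cfg, rate_cb, lambda rng: (0, 0),
                                  lambda st, rng: (st, st))
    return tree


def simulate_episodic_tree(model: EpisodicModel,
                           config: SimulationConfig) -> Phylogeny:
    lam_i, mu_i = rates_from_rt(model.rates, model.turnovers)

    def rate_cb(age, states):
        n = len(states)
        idx = int(model.interval_of(age))
        return np.full(n, lam_i[idx]), np.full(n, mu_i[idx]), None

    cfg = SimulationConfig(**{**asdict(config), "f": model.f}) \
        if config.f == 1.0 and model.f != 1.0 else config
    tree, _, _ = _run_conditioned(cfg, rate_cb, lambda rng: (0, 0),
                                  lambda st, rng: (st, st))
    return tree


def simulate_dd_tree(model: DDModel, config: SimulationConfig) -> Phylogeny:
    def rate_cb(age, states):
        n = len(states)
        return (np.full(n, float(model.lam(n))),
                np.full(n, float(model.mu(n))), None)

    cfg = SimulationConfig(**{**asdict(config), "f": model.f}) \
        if config.f == 1.0 and model.f != 1.0 else config
    tree, _, _ = _run_conditioned(cfg, rate_cb, lambda rng: (0, 0),
                                  lambda st, rng: (st, st))
    return tree


def simulate_sse_tree(spec: SSEModelSpec, config: SimulationConfig,
                      return_log: bool = False):
    """Joint (tree, examined tip states) under an SSE model.

    Concealed states are simulated but only examined states are emitted.
    """
    lam = spec.lambda_by_state()
    mu = spec.mu_by_state()
    Q = spec.q_matrix()
    K = spec.n_states
    trans_rates = Q - np.diag(np.diag(Q))
    adj = _ADJACENCY[spec.structure]

    def rate_cb(age, states):
        st = np.asarray(states, dtype=int)
        return lam[st], mu[st], trans_rates[st]

    def clado_fn(state, rng):
        if spec.inheritance == "dual":
            return state, state
        c, e = divmod(state, N_EXAM)
        alts = adj[e]
        j = alts[rng.integers(len(alts))]
        other = c * N_EXAM + j
        return (state, other) if rng.random() < 0.5 else (other, state)

    def init_state_fn(rng):
        s = int(rng.integers(K))
        return s, s

    per_state_f = np.full(K, spec.f)
    tree, tip_states_comb, log = _run_conditioned(
        config, rate_cb, init_state_fn, clado_fn,
        per_state_f=per_state_f, want_states=True)
    tip_states = {k: v % N_EXAM for k, v in tip_states_comb.items()}
    if return_log:
        return tree, tip_states, log
    return tree, tip_states


# -- environmental curves and the study-shaped fixture -----------------------


def synthetic_env_curve(kind: str, seed: int = 0, age_span=(0.0, 25.0),
                        n: int = 126) -> EnvCurve:
    """Smooth proxy curves spanning the study's age range.

    cooling_trend: temperature-like, monotone increasing with age (past was
    warmer); oscillation: period 5 Myr; constant: flat.
    """
    rng = np.random.default_rng(seed)
    ages = np.linspace(age_span[0], age_span[1], n)
    if kind == "constant":
        vals = np.full(n, 15.0)
    elif kind == "cooling_trend":
        # positive derivative field -> strictly monotone in age
        rough = rng.normal(0, 1, n)
        kernel = np.exp(-0.5 * (np.linspace(-3, 3, 21)) ** 2)
        smooth = np.convolve(rough, kernel / kernel.sum(), mode="same")
        deriv = 0.45 + 0.25 * np.abs(smooth)
        vals = 12.0 + np.concatenate([[0.0], np.cumsum(
            deriv[:-1] * np.diff(ages))])
    elif kind == "oscillation":
        vals = 15.0 + 2.0 * np.sin(2 * np.pi * ages / 5.0) \
            + rng.normal(0, 0.05, n)
    else:
        raise ValueError(f"unknown curve kind {kind!r}")
    return make_env_interpolator(np.column_stack([ages, vals]))


@dataclass
class StudyFixture:
    tree: Phylogeny
    habitats: dict[str, int]
    env: EnvCurve
    clades: dict[str, list[str]]
    manifest: dict


def make_fixture_study(seed: int = 0) -> StudyFixture:
    """Study-shaped synthetic bundle: ~94-tip tree, crown ~20 Ma, two nested
    focal clades (~40 and ~54 tips), 3-state habitat labels, a temperature-
    like proxy curve over 0-25 Ma, sampling fraction 0.92.

    Clade II grows under linear diversity-dependence (lambda0 = 0.3, K = 70,
    crown 17.5 Ma); Clade I under an episodic model with two downshifts
    (2 and 17 Ma); the two clades join at a 20 Ma root. Habitats evolve under
    an all-rates-different Mk process.
    """
    rng = np.random.default_rng(seed)
    f = 0.92

    clade2 = simulate_dd_tree(
        DDModel("DDL", lambda0=0.3, K=70.0, f=f),
        SimulationConfig(seed=int(rng.integers(2**31)), crown_age=17.5, f=f,
                         conditioning="n_tips", target_tips=54,
                         tip_tolerance=0.12, max_attempts=2000))
    clade1 = simulate_episodic_tree(
        EpisodicModel(shift_times=[2.0, 17.0], rates=[0.013, 0.10, 0.548],
                      turnovers=[0.163, 0.6, 0.503], f=f),
        SimulationConfig(seed=int(rng.integers(2**31)), crown_age=18.0, f=f,
                         conditioning="n_tips", target_tips=40,
                         tip_tolerance=0.15, max_attempts=4000))

    root = Node()
    r1 = _relabel(clade1.root, "CladeI_sp")
    r2 = _relabel(clade2.root, "CladeII_sp")
    r1.length = 20.0 - clade1.crown_age
    r2.length = 20.0 - clade2.crown_age
    r1.parent = r2.parent = root
    root.children = [r1, r2]
    tree = Phylogeny(root)

    from .mk import build_q  # deferred import: mk does not depend on us

    Qhab = build_q("ARD", [0.08, 0.005, 0.10, 0.026, 0.004, 0.06])
    habitats = None
    hab_rng = np.random.default_rng(seed + 1000)
    for _ in range(50):
        root_state = int(hab_rng.choice(3, p=[0.6, 0.3, 0.1]))
        tips = _simulate_mk_forward(tree, Qhab, root_state, hab_rng)
        if len(set(tips.values())) == 3:
            habitats = tips
            break
    if habitats is None:  # pragma: no cover
        raise SimulationError("could not place all three habitat states")

    env = synthetic_env_curve("cooling_trend", seed=seed + 7)
    clades = {
        "Clade_I": sorted(t for t in tree.tip_labels if t.startswith("CladeI_")),
        "Clade_II": sorted(t for t in tree.tip_labels if t.startswith("CladeII_")),
    }
    manifest = {
        "seed": seed, "f": f, "crown_age": 20.0,
        "clade_II": {"model": "DDL", "lambda0": 0.3, "K": 70.0,
                     "crown_age": 17.5},
        "clade_I": {"model": "episodic-2-shift", "shifts": [2.0, 17.0],
                    "crown_age": 18.0},
        "habitat_Q": Qhab.tolist(),
        "n_tips": tree.n_tips,
    }
    return StudyFixture(tree=tree, habitats=habitats, env=env,
                        clades=clades, manifest=manifest)


def _relabel(root, prefix):
    i = 0
    for tip in _iter_tips(root):
        i += 1
        tip.label = f"{prefix}{i:02d}"
    return root


def write_fixture(fixture: StudyFixture, outdir) -> Path:
    """Write the fixture bundle: tree.nwk, habitats.tsv, env_temperature.csv,
    clades.json and a manifest with the seed and parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "tree.nwk").write_text(fixture.tree.write_newick() + "\n")
    pd.DataFrame(
        {"taxon": list(fixture.habitats),
         "habitat": [STATES[s] for s in fixture.habitats.values()]}
    ).to_csv(outdir / "habitats.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"age_Ma": fixture.env.ages, "value": fixture.env.values}
    ).to_csv(outdir / "env_temperature.csv", index=False)
    (outdir / "clades.json").write_text(json.dumps(fixture.clades, indent=1))
    (outdir / "manifest.json").write_text(json.dumps(fixture.manifest, indent=1))
    return outdir


def _simulate_mk_forward(tree: Phylogeny, Q: np.ndarray, root_state: int,
                         rng) -> dict[str, int]:
    """Plain forward CTMC simulation of a character along the tree."""
    out = {}
    rates = -np.diag(Q)

    def walk(node, state):
        t = 0.0
        while True:
            r = rates[state]
            if r <= 0:
                break
            t += rng.exponential(1.0 / r)
            if t >= node.length:
                break
            probs = Q[state].copy()
            probs[state] = 0.0
            state = int(rng.choice(3, p=probs / probs.sum()))
        if node.is_tip:
            out[node.label] = state
        for ch in node.children:
            walk(ch, state)

    for ch in tree.root.children:
        walk(ch, root_state)
    return out
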