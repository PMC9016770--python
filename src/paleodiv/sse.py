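"""Hidden-state trait-dependent speciation-extinction (SSE) models.

The state space is the product of 3 examined habitat states (forest,
intermediate, open) and d concealed states. Speciation rates are tied across
concealed states and free across examined states (ETD), the reverse (CTD),
or a single value (CR); extinction is one shared rate by default. Anagenetic
habitat change follows one of six transition structures (the constrained
ones forbid direct forest <-> open moves); concealed states flip at one
shared rate. Cladogenesis is dual (both daughters inherit the parent's
habitat) or single (exactly one daughter inherits it; the other takes any
other habitat permitted by the structure's adjacency, the speciation rate
split equally among the alternatives, conserving total lambda).

Per-branch ODEs on the extinction vector E_s and likelihood vector D_s over
combined states s (Dormand-Prince 4(5), compiled with numba):

    dE_s/dt = mu_s - (lam_s + mu_s) E_s + (Q E)_s + sum_c r_c E_a E_b
    dD_s/dt = -(lam_s + mu_s) D_s + (Q D)_s + sum_c r_c (D_a E_b + E_a D_b)

with the cladogenetic tensor summing to lam_s for each parent state. Tips:
D = f on the observed habitat for every concealed state, E = 1 - f. Root
states are weighted by conditional likelihoods and the likelihood is
conditioned on survival of both crown lineages.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.optimize import minimize

from .bd import FitResult, LikelihoodError
from .mk import STATES
from .phylo import Phylogeny

__all__ = [
    "SSEModelSpec", "STRUCTURES", "enumerate_model_space", "sse_loglik",
    "fit_sse", "node_state_probs", "validate_by_simulation",
]

N_EXAM = 3

STRUCTURES = (
    "Unconstrained1", "Unconstrained6", "Constrained1",
    "Constrained4", "ConstrainedSpecialist", "ConstrainedOpenness",
)

_N_EXAM_TRANS = {
    "Unconstrained1": 1, "Unconstrained6": 6, "Constrained1": 1,
    "Constrained4": 4, "ConstrainedSpecialist": 2, "ConstrainedOpenness": 2,
}

# off-diagonal (from, to) slots each structure assigns to each free rate
_STRUCT_SLOTS = {
    "Unconstrained1": [[(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]],
    "Unconstrained6": [[(0, 1)], [(0, 2)], [(1, 0)], [(1, 2)], [(2, 0)], [(2, 1)]],
    "Constrained1": [[(0, 1), (1, 0), (1, 2), (2, 1)]],
    "Constrained4": [[(0, 1)], [(1, 0)], [(2, 1)], [(1, 2)]],
    "ConstrainedSpecialist": [[(1, 0), (1, 2)], [(0, 1), (2, 1)]],
    "ConstrainedOpenness": [[(0, 1), (1, 2)], [(2, 1), (1, 0)]],
}

# habitats reachable in one move (single-inheritance daughter alternatives)
_ADJACENCY = {
    "Unconstrained1": {0: (1, 2), 1: (0, 2), 2: (0, 1)},
    "Unconstrained6": {0: (1, 2), 1: (0, 2), 2: (0, 1)},
}
_CONSTRAINED_ADJ = {0: (1,), 1: (0, 2), 2: (1,)}
for _s in ("Constrained1", "Constrained4", "ConstrainedSpecialist",
           "ConstrainedOpenness"):
    _ADJACENCY[_s] = _CONSTRAINED_ADJ


@dataclass(frozen=True)
class SSEModelSpec:
    """Model structure plus (optionally) its rate values.

    Combined-state index: s = concealed * 3 + examined.
    """

    dependence: str                  # ETD | CTD | CR
    inheritance: str                 # dual | single
    structure: str
    d: int = 3                       # concealed-state count
    f: float = 0.92                  # sampling fraction (per state, shared)
    lam: tuple | None = None         # length n_lambda
    mu: float | None = None          # shared extinction
    exam_rates: tuple | None = None  # length n_exam_trans
    conc_rate: float | None = None   # shared concealed-flip rate
    root_weighting: str = "conditional"   # conditional | uniform
    conditioning: bool = True

    def __post_init__(self):
        if self.dependence not in ("ETD", "CTD", "CR"):
            raise ValueError(f"unknown dependence {self.dependence!r}")
        if self.inheritance not in ("dual", "single"):
            raise ValueError(f"unknown inheritance {self.inheritance!r}")
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")

    # -- bookkeeping --------------------------------------------------------

    @property
    def n_lambda(self) -> int:
        return {"ETD": N_EXAM, "CTD": self.d, "CR": 1}[self.dependence]

    @property
    def n_exam_trans(self) -> int:
        return _N_EXAM_TRANS[self.structure]

    @property
    def n_params(self) -> int:
        # lambdas + shared mu + examined transitions + shared concealed rate
        conc = 1 if self.d > 1 else 0
        return self.n_lambda + 1 + self.n_exam_trans + conc

    @property
    def n_states(self) -> int:
        return N_EXAM * self.d

    @property
    def label(self) -> str:
        return f"{self.dependence}-{self.inheritance}-{self.structure}"

    def with_params(self, theta) -> "SSEModelSpec":
        """Attach a flat parameter vector (lam.., mu, exam_rates.., conc)."""
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.n_params:
            raise ValueError(f"{self.label}: expected {self.n_params} params")
        nl, nt = self.n_lambda, self.n_exam_trans
        lam = tuple(theta[:nl])
        mu = float(theta[nl])
        ex = tuple(theta[nl + 1: nl + 1 + nt])
        conc = float(theta[nl + 1 + nt]) if self.d > 1 else 0.0
        return replace(self, lam=lam, mu=mu, exam_rates=ex, conc_rate=conc)

    # -- rate arrays over combined states -----------------------------------

    def lambda_by_state(self) -> np.ndarray:
        lam = np.zeros(self.n_states)
        for c in range(self.d):
            for e in range(N_EXAM):
                s = c * N_EXAM + e
                if self.dependence == "ETD":
                    lam[s] = self.lam[e]
                elif self.dependence == "CTD":
                    lam[s] = self.lam[c]
                else:
                    lam[s] = self.lam[0]
        return lam

    def mu_by_state(self) -> np.ndarray:
        return np.full(self.n_states, self.mu)

    def q_matrix(self) -> np.ndarray:
        K = self.n_states
        Qe = np.zeros((N_EXAM, N_EXAM))
        for rate, slots in zip(self.exam_rates, _STRUCT_SLOTS[self.structure]):
            for (i, j) in slots:
                Qe[i, j] = rate
        Q = np.zeros((K, K))
        for c in range(self.d):
            base = c * N_EXAM
            Q[base:base + N_EXAM, base:base + N_EXAM] = Qe
        if self.d > 1:
            for c1, c2 in itertools.permutations(range(self.d), 2):
                for e in range(N_EXAM):
                    Q[c1 * N_EXAM + e, c2 * N_EXAM + e] = self.conc_rate
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def clado_events(self):
        """Ordered cladogenetic events (parent, daughter_a, daughter_b, rate).

        Rates over all ordered daughter pairs of a parent sum to lam(parent).
        """
        lam = self.lambda_by_state()
        par, da, db, rate = [], [], [], []
        for c in range(self.d):
            for e in range(N_EXAM):
                s = c * N_EXAM + e
                if self.inheritance == "dual":
                    par.append(s), da.append(s), db.append(s), rate.append(lam[s])
                else:
                    alts = _ADJACENCY[self.structure][e]
                    L = len(alts)
                    for j in alts:
                        sj = c * N_EXAM + j
                        for aa, bb in ((s, sj), (sj, s)):
                            par.append(s), da.append(aa), db.append(bb)
                            rate.append(lam[s] / (2.0 * L))
        return (np.array(par, dtype=np.int64), np.array(da, dtype=np.int64),
                np.array(db, dtype=np.int64), np.array(rate, dtype=float))


def enumerate_model_space(d: int = 3, f: float = 0.92) -> list[SSEModelSpec]:
    """The 36 structure combinations: {ETD, CTD, CR} x {dual, single} x 6."""
    return [
        SSEModelSpec(dep, inh, st, d=d, f=f)
        for dep in ("ETD", "CTD", "CR")
        for inh in ("dual", "single")
        for st in STRUCTURES
    ]


# -- numba ODE kernel --------------------------------------------------------

@njit(cache=True)
def _rhs(y, K, lam, mu, Q, cpar, ca, cb, crate, out):
    for i in range(K):
        qe = 0.0
        qd = 0.0
        for j in range(K):
            qe += Q[i, j] * y[j]
            qd += Q[i, j] * y[K + j]
        out[i] = mu[i] - (lam[i] + mu[i]) * y[i] + qe
        out[K + i] = -(lam[i] + mu[i]) * y[K + i] + qd
    for e in range(cpar.shape[0]):
        i = cpar[e]
        a = ca[e]
        b = cb[e]
        r = crate[e]
        out[i] += r * y[a] * y[b]
        out[K + i] += r * (y[K + a] * y[b] + y[a] * y[K + b])


@njit(cache=True)
def _rhs_up(y, K, lam, mu, Q, cpar, ca, cb, crate, out):
    """Reverse-time (root-to-tip) propagation of an 'above' partial U.

    y = [E, U] parameterized by sigma = parent_age - age. E runs backward
    (negated RHS); U follows the adjoint of D's linear propagator:
    dU/dsigma = A(E)^T U with A the coefficient matrix of dD/dt = A D.
    """
    for i in range(K):
        qe = 0.0
        qtu = 0.0
        for j in range(K):
            qe += Q[i, j] * y[j]
            qtu += Q[j, i] * y[K + j]
        out[i] = -(mu[i] - (lam[i] + mu[i]) * y[i] + qe)
        out[K + i] = -(lam[i] + mu[i]) * y[K + i] + qtu
    for e in range(cpar.shape[0]):
        i = cpar[e]
        a = ca[e]
        b = cb[e]
        r = crate[e]
        out[i] -= r * y[a] * y[b]
        out[K + a] += r * y[K + i] * y[b]
        out[K + b] += r * y[K + i] * y[a]


@njit(cache=True)
def _rhs_dispatch(mode, y, K, lam, mu, Q, cpar, ca, cb, crate, out):
    if mode == 0:
        _rhs(y, K, lam, mu, Q, cpar, ca, cb, crate, out)
    else:
        _rhs_up(y, K, lam, mu, Q, cpar, ca, cb, crate, out)


@njit(cache=True)
def _integrate(y0, t_span, mode, K, lam, mu, Q, cpar, ca, cb, crate,
               rtol, atol):
    """Adaptive Dormand-Prince 4(5) over [0, t_span]. mode 0: tip-to-root
    [E, D] system; mode 1: root-to-tip adjoint [E, U] system."""
    y = y0.copy()
    n = y.shape[0]
    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n); k4 = np.empty(n)
    k5 = np.empty(n); k6 = np.empty(n); k7 = np.empty(n)
    ytmp = np.empty(n)
    t = 0.0
    h = min(0.1, t_span) if t_span > 0 else 0.0
    _rhs_dispatch(mode, y, K, lam, mu, Q, cpar, ca, cb, crate, k1)
    nsteps = 0
    while t < t_span and nsteps < 20000:
        nsteps += 1
        if t + h > t_span:
            h = t_span - t
        s = h
        for i in range(n):
            ytmp[i] = y[i] + s * 0.2 * k1[i]
        _rhs_dispatch(mode, ytmp, K, lam, mu, Q, cpar, ca, cb, crate, k2)
        for i in range(n):
            ytmp[i] = y[i] + s * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
        _rhs_dispatch(mode, ytmp, K, lam, mu, Q, cpar, ca, cb, crate, k3)
        for i in range(n):
            ytmp[i] = y[i] + s * (44.0 / 45.0 * k1[i] - 56.0 / 15.0 * k2[i]
                                  + 32.0 / 9.0 * k3[i])
        _rhs_dispatch(mode, ytmp, K, lam, mu, Q, cpar, ca, cb, crate, k4)
        for i in range(n):
            ytmp[i] = y[i] + s * (19372.0 / 6561.0 * k1[i]
                                  - 25360.0 / 2187.0 * k2[i]
                                  + 64448.0 / 6561.0 * k3[i]
                                  - 212.0 / 729.0 * k4[i])
        _rhs_dispatch(mode, ytmp, K, lam, mu, Q, cpar, ca, cb, crate, k5)
        for i in range(n):
            ytmp[i] = y[i] + s * (9017.0 / 3168.0 * k1[i]
                                  - 355.0 / 33.0 * k2[i]
                                  + 46732.0 / 5247.0 * k3[i]
                                  + 49.0 / 176.0 * k4[i]
                                  - 5103.0 / 18656.0 * k5[i])
        _rhs_dispatch(mode, ytmp, K, lam, mu, Q, cpar, ca, cb, crate, k6)
        for i in range(n):
            ytmp[i] = y[i] + s * (35.0 / 384.0 * k1[i]
                                  + 500.0 / 1113.0 * k3[i]
                                  + 125.0 / 192.0 * k4[i]
                                  - 2187.0 / 6784.0 * k5[i]
                                  + 11.0 / 84.0 * k6[i])
        _rhs_dispatch(mode, ytmp, K, lam, mu, Q, cpar, ca, cb, crate, k7)
        errnorm = 0.0
        for i in range(n):
            e5 = (71.0 / 57600.0 * k1[i] - 71.0 / 16695.0 * k3[i]
                  + 71.0 / 1920.0 * k4[i] - 17253.0 / 339200.0 * k5[i]
                  + 22.0 / 525.0 * k6[i] - 1.0 / 40.0 * k7[i])
            sc = atol + rtol * max(abs(y[i]), abs(ytmp[i]))
            q = h * e5 / sc
            errnorm += q * q
        errnorm = np.sqrt(errnorm / n)
        if errnorm <= 1.0:
            t += h
            for i in range(n):
                y[i] = ytmp[i]
                k1[i] = k7[i]
        fac = 0.9 * errnorm ** (-0.2) if errnorm > 0 else 5.0
        if fac > 5.0:
            fac = 5.0
        if fac < 0.2:
            fac = 0.2
        h *= fac
        if h < 1e-12:
            h = 1e-12
    if t < t_span - 1e-9 * (t_span + 1.0):
        for i in range(n):
            y[i] = np.nan
    return y


def _spec_arrays(spec: SSEModelSpec):
    lam = spec.lambda_by_state()
    mu = spec.mu_by_state()
    if np.any(lam < 0) or np.any(mu < 0):
        raise LikelihoodError("negative SSE rates")
    Q = spec.q_matrix()
    cpar, ca, cb, crate = spec.clado_events()
    return lam, mu, Q, cpar, ca, cb, crate


def _merge(spec_arrays, D1, E1, D2):
    """Combine daughter likelihoods at a node via the cladogenetic tensor."""
    lam, mu, Q, cpar, ca, cb, crate = spec_arrays
    D = np.zeros_like(D1)
    np.add.at(D, cpar, crate * (D1[ca] * D2[cb]))
    return D


def _postorder_pass(tree, tip_states, spec, rtol, atol, clamp=None):
    """Down-pass; returns (D_root, E_root, logscale, stores) where stores maps
    node-id -> (D_merged, E_at_node) for every internal node."""
    arrays = _spec_arrays(spec)
    lam, mu, Q, cpar, ca, cb, crate = arrays
    K = spec.n_states
    f = spec.f
    stores = {}
    logscale = 0.0
    partial = {}
    exam_of = np.arange(K) % N_EXAM
    for node in tree.postorder():
        if node.is_tip:
            if node.label not in tip_states:
                raise ValueError(f"tip {node.label!r} has no habitat state")
            E = np.full(K, 1.0 - f)
            D = np.where(exam_of == tip_states[node.label], f, 0.0)
        else:
            (D1, E1), (D2, E2) = (partial.pop(id(c)) for c in node.children)
            D = _merge(arrays, D1, E1, D2)
            E = E1  # E is a global function of age; either child matches
        if clamp is not None and id(node) == clamp[0]:
            D = np.where(exam_of == clamp[1], D, 0.0)
        s = D.sum()
        if s <= 0 or not np.isfinite(s):
            return None, None, -np.inf, stores
        D = D / s
        logscale += np.log(s)
        stores[id(node)] = (D.copy(), E.copy())
        if node.parent is not None:
            y0 = np.concatenate([E, D])
            y = _integrate(y0, node.length, 0, K, lam, mu, Q,
                           cpar, ca, cb, crate, rtol, atol)
            partial[id(node)] = (y[K:].copy(), y[:K].copy())
        else:
            partial[id(node)] = (D, E)
    D_root, E_root = partial[id(tree.root)]
    return D_root, E_root, logscale, stores


def sse_loglik(tree: Phylogeny, tip_states: dict, spec: SSEModelSpec,
               rtol: float = 1e-8, atol: float = 1e-10,
               _clamp=None) -> float:
    """Log-likelihood of the tree and habitat states under an SSE model."""
    if spec.lam is None:
        raise ValueError("spec carries no parameter values; use with_params")
    D, E, logscale, _ = _postorder_pass(tree, tip_states, spec, rtol, atol,
                                        clamp=_clamp)
    if not np.isfinite(logscale):
        return -np.inf
    lam = spec.lambda_by_state()
    if spec.root_weighting == "conditional":
        w = D / D.sum()
    else:
        w = np.full(spec.n_states, 1.0 / spec.n_states)
    if spec.conditioning:
        denom = lam * (1.0 - E) ** 2
        good = denom > 0
        L = float(np.sum(np.where(good, w * D / np.where(good, denom, 1.0), 0.0)))
    else:
        L = float(w @ D)
    if L <= 0 or not np.isfinite(L):
        return -np.inf
    return float(np.log(L) + logscale)


def fit_sse(tree: Phylogeny, tip_states: dict, spec: SSEModelSpec,
            n_starts: int = 3, seed: int = 0, rtol: float = 1e-7,
            atol: float = 1e-9) -> FitResult:
    """ML fit of one SSE model; best of n_starts local optimizations.

    Rates are optimized on a log scale; AICc uses n = number of tips.
    """
    n_tips = tree.n_tips
    T = tree.crown_age
    lam_scale = max(np.log(max(n_tips / spec.f, 4) / 2.0) / T, 1e-3)
    q_scale = 0.1 * lam_scale
    rng = np.random.default_rng(seed)

    nl, nt = spec.n_lambda, spec.n_exam_trans
    base = np.concatenate([
        np.full(nl, np.log(lam_scale)),
        [np.log(0.1 * lam_scale)],
        np.full(nt, np.log(q_scale)),
        [np.log(q_scale)] if spec.d > 1 else [],
    ])

    def nll(x):
        try:
            s = spec.with_params(np.exp(x))
            return -sse_loglik(tree, tip_states, s, rtol, atol)
        except (LikelihoodError, ValueError):
            return 1e10

    best = None
    n_ok = 0
    log_bounds = [(np.log(1e-8), np.log(50.0))] * base.size
    for i in range(n_starts):
        x0 = base if i == 0 else base + rng.normal(0, 1.0, base.size)
        res = minimize(nll, x0, method="Nelder-Mead", bounds=log_bounds,
                       options={"xatol": 1e-6, "fatol": 1e-7,
                                "maxiter": 300 * base.size})
        if np.isfinite(res.fun) and res.fun < 1e9:
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        return FitResult(spec.label, -np.inf, {}, spec.n_params,
                         converged=False, n_starts_used=0)
    theta = np.exp(best.x)
    fitted = spec.with_params(theta)
    params = {f"lambda_{i}": float(v) for i, v in enumerate(fitted.lam)}
    params["mu"] = fitted.mu
    for i, v in enumerate(fitted.exam_rates):
        params[f"q_exam_{i}"] = float(v)
    if spec.d > 1:
        params["q_concealed"] = fitted.conc_rate
    return FitResult(
        spec.label, -float(best.fun), params, spec.n_params, converged=True,
        n_starts_used=n_ok,
        metadata={"d": spec.d, "f": spec.f, "aicc_n": n_tips,
                  "root_weighting": spec.root_weighting,
                  "fitted_spec": fitted},
    )


def node_state_probs(tree: Phylogeny, tip_states: dict, spec: SSEModelSpec,
                     rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    """Per-internal-node probabilities over examined states (concealed states
    marginalized out); rows align with ``tree.internal_nodes()``.

    Down-pass D vectors are combined with an up-pass that integrates the
    same linear propagation in reverse along each branch.
    """
    arrays = _spec_arrays(spec)
    lam, mu, Q, cpar, ca, cb, crate = arrays
    K = spec.n_states
    D_root, E_root, logscale, stores = _postorder_pass(
        tree, tip_states, spec, rtol, atol)
    if not np.isfinite(logscale):
        raise LikelihoodError("zero likelihood; cannot compute node state probs")
    if spec.root_weighting == "conditional":
        U_root = D_root / D_root.sum()
    else:
        U_root = np.full(K, 1.0 / K)
    up = {id(tree.root): U_root}
    for node in tree.preorder():
        if node.is_tip:
            continue
        U = up[id(node)]
        c1, c2 = node.children
        for child, sib in ((c1, c2), (c2, c1)):
            # daughter partials at the parent's age
            Ds_age = _branch_partial(stores, sib, node, arrays, K, spec,
                                     rtol, atol)
            Utilde = np.zeros(K)
            np.add.at(Utilde, ca, crate * U[cpar] * Ds_age[cb])
            if child.is_tip and child.length == 0:
                up[id(child)] = Utilde
                continue
            E_par = stores[id(node)][1]
            y0 = np.concatenate([E_par, Utilde])
            y = _integrate(y0, child.length, 1, K, lam, mu, Q,
                           cpar, ca, cb, crate, rtol, atol)
            U_child = np.maximum(y[K:], 0.0)
            s = U_child.sum()
            up[id(child)] = U_child / s if s > 0 else U_child
    out = []
    for node in tree.internal_nodes():
        m = stores[id(node)][0] * up[id(node)]
        m = m.reshape(spec.d, N_EXAM).sum(axis=0)
        out.append(m / m.sum())
    return np.array(out)


def _branch_partial(stores, child, parent, arrays, K, spec, rtol, atol):
    """D of `child` propagated along its branch to the parent's age."""
    lam, mu, Q, cpar, ca, cb, crate = arrays
    D, E = stores[id(child)]
    y0 = np.concatenate([E, D])
    y = _integrate(y0, child.length, 0, K, lam, mu, Q, cpar, ca, cb, crate,
                   rtol, atol)
    return y[K:]


def validate_by_simulation(etd_spec: SSEModelSpec, ctd_spec: SSEModelSpec,
                           target_tips: int, n_sims: int = 30, seed: int = 0,
                           n_starts: int = 1, fit_d: int | None = None):
    """Simulate under each fitted model, refit both, count correct selections.

    Crown age per replicate is tuned so reconstructed trees are similar in
    size to the target tip count. Model choice is by raw log-likelihood, as
    in the validation protocol. Returns a confusion DataFrame
    (rows = generating model, columns = selected model).
    """
    import pandas as pd

    from .simulate import SimulationConfig, simulate_sse_tree

    confusion = {("ETD", "ETD"): 0, ("ETD", "CTD"): 0,
                 ("CTD", "ETD"): 0, ("CTD", "CTD"): 0}
    for gen_name, gen_spec in (("ETD", etd_spec), ("CTD", ctd_spec)):
        if gen_spec.lam is None:
            raise ValueError(f"{gen_name} spec carries no fitted parameters")
        lam_bar = float(np.mean(gen_spec.lambda_by_state()))
        r = max(lam_bar - gen_spec.mu, 1e-3)
        T = np.log(max(target_tips * gen_spec.f, 4) / 2.0) / r
        for rep in range(n_sims):
            cfg = SimulationConfig(
                seed=seed * 100003 + rep * 17 + (0 if gen_name == "ETD" else 7),
                crown_age=T, f=gen_spec.f, conditioning="n_tips",
                target_tips=target_tips, tip_tolerance=0.3, max_attempts=200,
            )
            tree, tips = simulate_sse_tree(gen_spec, cfg)
            d_fit = fit_d
            fits = {}
            for name, sp in (("ETD", etd_spec), ("CTD", ctd_spec)):
                sp_fit = replace(sp, lam=None, mu=None, exam_rates=None,
                                 conc_rate=None,
                                 d=d_fit if d_fit is not None else sp.d)
                fits[name] = fit_sse(tree, tips, sp_fit, n_starts=n_starts,
                                     seed=cfg.seed + 1)
            chosen = "ETD" if fits["ETD"].loglik >= fits["CTD"].loglik else "CTD"
            confusion[(gen_name, chosen)] += 1
    return pd.DataFrame(
        [[confusion[("ETD", "ETD")], confusion[("ETD", "CTD")]],
         [confusion[("CTD", "ETD")], confusion[("CTD", "CTD")]]],
        index=pd.Index(["ETD", "CTD"], name="generating"),
        columns=pd.Index(["ETD", "CTD"], name="selected"),
    )
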