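"""Diversity-dependent birth-death likelihoods (species-count master equation).

Five standard variants, with n the current total number of species:

    DDL    lambda(n) = max(lambda0 (1 - n/K), 0),            mu = 0
    DDL+E  lambda(n) = max(lambda0 - (lambda0-mu0) n/K, 0),  mu = mu0
    DDX+E  lambda(n) = lambda0 n^-x,                         mu = mu0
    DD+EL  lambda = lambda0,  mu(n) = mu0 + (lambda0-mu0) n/K
    DD+EX  lambda = lambda0,  mu(n) = mu0 n^x

The likelihood evolves the probability vector over the number m of "hidden"
coexisting species (extant species not ancestral to a sampled tip) between
consecutive branching times, forward in time from the crown (k = 2, m = 0):

    up   m -> m+1 at lambda(n) * (m + 2k)   (hidden births; observed-lineage
                                             births carry multiplicity 2 since
                                             either daughter may continue the
                                             observed path)
    down m -> m-1 at mu(n) * m              (hidden lineages may die)
    diag         - n (lambda(n) + mu(n))    (event outflow; observed-lineage
                                             deaths leak probability)

with n = k + m. Each observed branching multiplies by lambda(n) and sets
k -> k+1; at the present, hidden survivors weigh (1-f)^m and tips f^k.
Conditioning on survival of both crown lineages uses a 2-D master equation
over the pair of crown-subclade sizes (exactly 1 when mu = 0 and f = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.optimize import minimize

from .bd import FitResult, LikelihoodError

__all__ = ["DDModel", "dd_loglik", "fit_dd_family", "DD_VARIANTS"]

DD_VARIANTS = ("DDL", "DDL+E", "DDX+E", "DD+EL", "DD+EX")

_TRUNC_CAP = 2000       # hard cap on master-equation truncation
_COND_TRUNC = 200       # per-subclade cap in the 2-D conditioning equation


@dataclass
class DDModel:
    variant: str
    lambda0: float
    mu0: float = 0.0
    K: float | None = None
    x: float | None = None
    f: float = 0.92
    conditioning: str = "crown_survival"

    def __post_init__(self):
        if self.variant not in DD_VARIANTS:
            raise ValueError(f"unknown DD variant {self.variant!r}")
        if self.variant == "DDL":
            self.mu0 = 0.0
        if self.variant in ("DDL", "DDL+E", "DD+EL"):
            if self.K is None or self.K <= 1:
                raise ValueError("linear diversity dependence requires K > 1")
        if self.variant in ("DDX+E", "DD+EX") and (self.x is None or self.x <= 0):
            raise ValueError("exponent variants require x > 0")
        if self.lambda0 < 0 or self.mu0 < 0:
            raise ValueError("rates must be nonnegative")

    def lam(self, n):
        n = np.asarray(n, dtype=float)
        if self.variant in ("DDL", "DDL+E"):
            return np.maximum(self.lambda0 - (self.lambda0 - self.mu0) * n / self.K, 0.0)
        if self.variant == "DDX+E":
            return self.lambda0 * np.maximum(n, 1.0) ** (-self.x)
        return self.lambda0 * np.ones_like(n)

    def mu(self, n):
        n = np.asarray(n, dtype=float)
        if self.variant == "DD+EL":
            return np.maximum(self.mu0 + (self.lambda0 - self.mu0) * n / self.K, 0.0)
        if self.variant == "DD+EX":
            return self.mu0 * np.maximum(n, 1.0) ** self.x
        return self.mu0 * np.ones_like(n)

    @property
    def mu_is_zero(self) -> bool:
        return self.variant == "DDL" or (
            self.mu0 == 0.0 and self.variant in ("DDL+E", "DDX+E"))


def _default_truncation(model: DDModel, n_tips: int) -> int:
    base = n_tips + 200
    if model.K is not None:
        base = max(int(np.ceil(2 * model.K)), base)
    if model.variant == "DD+EX" and model.mu0 > 0 and model.x > 0:
        # extinction grows as n^x: states far above the deterministic
        # equilibrium are unreachable but blow up the generator norm
        log_neq = np.log(max(model.lambda0, 1e-12) / model.mu0) / model.x
        n_eq = float(np.exp(min(log_neq, 20.0)))
        if 3 * n_eq + 10 < base:
            base = max(n_tips + 50, int(3 * n_eq) + 10)
    return min(base, _TRUNC_CAP)


def _pure_birth_loglik(bt_desc, model: DDModel) -> float:
    """Closed form for mu = 0, f = 1: no hidden lineages can exist."""
    n = bt_desc.size + 1
    ll = 0.0
    ages = np.concatenate([bt_desc, [0.0]])
    for i in range(n - 1):                   # interval with k = i+2 lineages
        k = i + 2
        lam_k = float(model.lam(k))
        ll -= lam_k * k * (ages[i] - ages[i + 1])
        if i < n - 2:                        # branching at ages[i+1], k lineages before
            if lam_k <= 0:
                return -np.inf
            ll += np.log(lam_k)
    return float(ll)


@njit(cache=True)
def _tridiag_uniform_expm(up, diag, down, v0, t, chunk=30.0):
    """e^{At} v for the tridiagonal generator, by uniformization.

    A[i+1, i] = up[i], A[i, i] = diag[i], A[i, i+1] = down[i+1].
    Returns NaNs if the generator norm is intractably large.
    """
    n = v0.shape[0]
    v = v0.copy()
    omega = -diag.min() * 1.01 + 1e-12
    if omega * t > 3e5 or omega * t * n > 3e8:
        return v * np.nan
    if omega <= 0 or t <= 0:
        return v
    n_seg = int(np.ceil(omega * t / chunk))
    if n_seg < 1:
        n_seg = 1
    tau = t / n_seg
    mu_pois = omega * tau
    j_max = int(mu_pois + 12.0 * np.sqrt(mu_pois) + 20)
    term = np.empty(n)
    nxt = np.empty(n)
    for _ in range(n_seg):
        scale = np.exp(-mu_pois)
        for i in range(n):
            term[i] = v[i] * scale
            v[i] = term[i]
        for j in range(1, j_max + 1):
            c = mu_pois / j
            for i in range(n):
                acc = term[i] + diag[i] * term[i] / omega
                if i > 0:
                    acc += up[i - 1] * term[i - 1] / omega
                if i < n - 1:
                    acc += down[i + 1] * term[i + 1] / omega
                nxt[i] = acc * c
            tot_term = 0.0
            tot_out = 0.0
            for i in range(n):
                term[i] = nxt[i]
                v[i] += nxt[i]
                tot_term += abs(nxt[i])
                tot_out += abs(v[i])
            if j > mu_pois and tot_term < 1e-14 * (tot_out + 1e-300):
                break
    return v


def _dd_core(bt_desc, model: DDModel, M: int):
    """Evolve the hidden-count vector crown -> present; return (logL, tail)."""
    n_tips = bt_desc.size + 1
    v = np.zeros(M + 1)
    v[0] = 1.0
    log_scale = 0.0
    ages = np.concatenate([bt_desc, [0.0]])
    max_tail = 0.0
    for i in range(n_tips - 1):
        k = i + 2
        dt = ages[i] - ages[i + 1]
        if dt > 0:
            m = np.arange(M + 1, dtype=float)
            n = k + m
            lam_n, mu_n = model.lam(n), model.mu(n)
            v = _tridiag_uniform_expm(lam_n * (m + 2 * k),
                                      -(lam_n * n + mu_n * n),
                                      mu_n * m, v, dt)
            if not np.all(np.isfinite(v)):
                raise LikelihoodError("generator norm too large")
            v = np.maximum(v, 0.0)
        tot = v.sum()
        if tot <= 0 or not np.isfinite(tot):
            return -np.inf, 0.0
        max_tail = max(max_tail, v[-3:].sum() / tot)
        log_scale += np.log(tot)
        v /= tot
        if i < n_tips - 2:                    # observed branching at ages[i+1]
            lam_b = np.asarray(model.lam(k + np.arange(M + 1)), dtype=float)
            v = v * lam_b
            s = v.sum()
            if s <= 0:
                return -np.inf, max_tail
            log_scale += np.log(s)
            v /= s
    weights = model.f ** n_tips * (1.0 - model.f) ** np.arange(M + 1)
    L = float(v @ weights)
    if L <= 0:
        return -np.inf, max_tail
    return log_scale + np.log(L), max_tail


@njit(cache=True)
def _pair_uniform_expm(lam_n, mu_n, M2, v0, t, chunk=30.0):
    """e^{At} v for the crown-subclade pair process on the (a, b) grid.

    Rates depend on n = a + b: births lam(n)*a (resp. *b), deaths mu(n)*a.
    Births at the grid boundary leak mass (boundary occupancy ~ 0).
    """
    v = v0.copy()
    omax = 0.0
    for aa in range(M2 + 1):
        for bb in range(M2 + 1):
            n = aa + bb
            d = (lam_n[n] + mu_n[n]) * n
            if d > omax:
                omax = d
    omega = omax * 1.01 + 1e-12
    if omega * t > 3e5 or omega * t * (M2 + 1.0) * (M2 + 1.0) > 2e8:
        return v * np.nan
    if omega <= 0 or t <= 0:
        return v
    n_seg = int(np.ceil(omega * t / chunk))
    if n_seg < 1:
        n_seg = 1
    tau = t / n_seg
    mu_pois = omega * tau
    j_max = int(mu_pois + 12.0 * np.sqrt(mu_pois) + 20)
    term = np.empty_like(v)
    nxt = np.empty_like(v)
    for _ in range(n_seg):
        scale = np.exp(-mu_pois)
        for i in range(v.shape[0]):
            for k in range(v.shape[1]):
                term[i, k] = v[i, k] * scale
                v[i, k] = term[i, k]
        for j in range(1, j_max + 1):
            c = mu_pois / j
            for aa in range(M2 + 1):
                for bb in range(M2 + 1):
                    n = aa + bb
                    acc = term[aa, bb] * (1.0 - (lam_n[n] + mu_n[n]) * n / omega)
                    if aa > 0:
                        acc += lam_n[n - 1] * (aa - 1) * term[aa - 1, bb] / omega
                    if bb > 0:
                        acc += lam_n[n - 1] * (bb - 1) * term[aa, bb - 1] / omega
                    if aa < M2:
                        acc += mu_n[n + 1] * (aa + 1) * term[aa + 1, bb] / omega
                    if bb < M2:
                        acc += mu_n[n + 1] * (bb + 1) * term[aa, bb + 1] / omega
                    nxt[aa, bb] = acc * c
            tot_term = 0.0
            tot_out = 0.0
            for aa in range(M2 + 1):
                for bb in range(M2 + 1):
                    term[aa, bb] = nxt[aa, bb]
                    v[aa, bb] += nxt[aa, bb]
                    tot_term += abs(nxt[aa, bb])
                    tot_out += abs(v[aa, bb])
            if j > mu_pois and tot_term < 1e-14 * (tot_out + 1e-300):
                break
    return v


def _conditioning_prob(model: DDModel, T: float, M: int) -> float:
    """P(both crown subclades have >= 1 sampled extant descendant).

    2-D master equation over subclade sizes (a, b), started at (1, 1).
    Each subclade is truncated a little above the carrying capacity
    (diversity rarely exceeds it), capped at _COND_TRUNC.
    """
    if model.mu_is_zero and model.f == 1.0:
        return 1.0
    # truncate each subclade a little above the deterministic equilibrium:
    # the pair process cannot plausibly exceed it, and the conditioning
    # scalar only needs ~1e-3 relative accuracy
    if model.K is not None:
        n_hi = 1.2 * model.K + 10
    elif model.variant in ("DDX+E", "DD+EX") and model.mu0 > 0:
        log_neq = np.log(max(model.lambda0, 1e-12) / model.mu0) / model.x
        n_hi = 2.0 * float(np.exp(min(log_neq, 12.0))) + 10
    else:
        n_hi = 150
    M2 = int(np.clip(n_hi, 40, min(M, _COND_TRUNC)))
    n_all = np.arange(2 * M2 + 2, dtype=float)
    lam_n = np.asarray(model.lam(n_all), dtype=float)
    mu_n = np.asarray(model.mu(n_all), dtype=float)
    v = np.zeros((M2 + 1, M2 + 1))
    v[1, 1] = 1.0
    v = _pair_uniform_expm(lam_n, mu_n, M2, v, T)
    if not np.all(np.isfinite(v)):
        raise LikelihoodError("conditioning generator norm too large")
    v = np.maximum(v, 0.0)
    w1 = 1.0 - (1.0 - model.f) ** np.arange(M2 + 1)
    return float(np.clip(w1 @ v @ w1, 1e-300, 1.0))


def dd_loglik(bt, model: DDModel, truncation: int | None = None) -> float:
    """Log-likelihood of branching times under a diversity-dependent model.

    The truncation bound auto-doubles (up to a cap) if probability mass
    accumulates at the boundary.
    """
    bt_desc = np.sort(np.asarray(bt, dtype=float))[::-1]
    n_tips = bt_desc.size + 1
    T = bt_desc[0]
    if model.mu_is_zero and model.f == 1.0:
        ll = _pure_birth_loglik(bt_desc, model)
        return ll  # conditioning = 1
    M = truncation or _default_truncation(model, n_tips)
    while True:
        ll, tail = _dd_core(bt_desc, model, M)
        if tail < 1e-8 or M >= _TRUNC_CAP:
            break
        M = min(2 * M, _TRUNC_CAP)
    if tail >= 1e-6 and M >= _TRUNC_CAP:
        raise LikelihoodError(
            f"master-equation truncation insufficient at cap {M}")
    if ll == -np.inf:
        return -np.inf
    if model.conditioning == "crown_survival":
        pc = _conditioning_prob(model, T, M)
        ll -= np.log(pc)
    return float(ll)


# -- fitting -----------------------------------------------------------------

_PARAMS = {
    "DDL": ("lambda0", "K"),
    "DDL+E": ("lambda0", "mu0", "K"),
    "DDX+E": ("lambda0", "mu0", "x"),
    "DD+EL": ("lambda0", "mu0", "K"),
    "DD+EX": ("lambda0", "mu0", "x"),
}

_DD_BOUNDS = {"lambda0": (1e-6, 10.0), "mu0": (0.0, 10.0),
              "K": (2.0, 1e4), "x": (1e-3, 3.0)}


def fit_dd_family(bt, f: float = 0.92, known_species: int | None = None,
                  variants=DD_VARIANTS, conditioning: str = "crown_survival",
                  n_starts: int = 3, seed: int = 0) -> list[FitResult]:
    """ML fits of the five DD variants, 3 starts each, best by AIC.

    The initial carrying capacity is set to the clade's known species count
    (defaulting to n_tips / f rounded up).
    """
    bt = np.sort(np.asarray(bt, dtype=float))[::-1]
    n_tips = bt.size + 1
    T = bt[0]
    if known_species is None:
        known_species = int(np.ceil(n_tips / f))
    if known_species < n_tips:
        raise ValueError("known_species must be >= the number of tips")
    rng = np.random.default_rng(seed)
    lam_scale = max(np.log(n_tips / 2.0) / T, 0.01)
    results = []
    for variant in variants:
        names = _PARAMS[variant]
        bounds = [_DD_BOUNDS[nm] for nm in names]

        def objective(xx, _variant=variant, _names=names):
            p = dict(zip(_names, xx))
            try:
                m = DDModel(_variant, p["lambda0"], p.get("mu0", 0.0),
                            p.get("K"), p.get("x"), f, conditioning)
                v = -dd_loglik(bt, m)
                return v if np.isfinite(v) else 1e10
            except (ValueError, LikelihoodError):
                return 1e10

        base = {"lambda0": 2.0 * lam_scale, "mu0": 0.2 * lam_scale,
                "K": float(known_species), "x": 0.5}
        best = None
        n_ok = 0
        for i in range(n_starts):
            x0 = np.array([base[nm] for nm in names])
            if i > 0:
                x0 = x0 * np.exp(rng.normal(0, 0.5, x0.size))
            x0 = np.array([np.clip(v, lo, hi) for v, (lo, hi) in zip(x0, bounds)])
            res = minimize(objective, x0, method="Nelder-Mead", bounds=bounds,
                           options={"xatol": 1e-6, "fatol": 1e-7, "maxiter": 3000})
            if np.isfinite(res.fun) and res.fun < 1e9:
                n_ok += 1
                if best is None or res.fun < best.fun:
                    best = res
        if best is None:
            results.append(FitResult(variant, -np.inf, {}, len(names),
                                     converged=False, n_starts_used=0))
            continue
        params = dict(zip(names, map(float, best.x)))
        results.append(FitResult(
            variant, -float(best.fun), params, len(names), converged=True,
            n_starts_used=n_ok,
            metadata={"f": f, "conditioning": conditioning,
                      "known_species": known_species,
                      "form": _form_string(variant)},
        ))
    return results


def _form_string(variant: str) -> str:
    return {
        "DDL": "lambda(n)=lambda0*(1-n/K); mu=0",
        "DDL+E": "lambda(n)=lambda0-(lambda0-mu0)*n/K; mu=mu0",
        "DDX+E": "lambda(n)=lambda0*n^-x; mu=mu0",
        "DD+EL": "lambda=lambda0; mu(n)=mu0+(lambda0-mu0)*n/K",
        "DD+EX": "lambda=lambda0; mu(n)=mu0*n^x",
    }[variant]
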