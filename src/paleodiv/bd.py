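"""Trait-free birth-death likelihoods on reconstructed ultrametric trees.

Speciation and extinction are constant, exponential in time, or exponential
in an interpolated paleoenvironmental curve:

    lambda(t) = lambda0 * exp(alpha * t)        (exp_time)
    lambda(t) = lambda0 * exp(alpha * env(t))   (exp_env)

with t the age in Ma. The reconstructed-tree likelihood follows the standard
coalescent-of-birth-death framework: the extinction probability E(t) solves

    dE/dt = mu(t) - (lambda(t) + mu(t)) E + lambda(t) E^2,   E(0) = 1 - f,

backward in time from the present, where f is the sampling fraction. Branch
contributions factor through Psi(s, t) = exp( int_s^t [2 lambda E - (lambda
+ mu)] ), so for an ultrametric tree the full log-likelihood is

    n log f + sum_{non-crown nodes} log lambda(t_i)
            + int_0^T k(t) [2 lambda E - (lambda + mu)] dt  -  conditioning,

with k(t) the number of reconstructed lineages at age t and the crown-
survival conditioning 2 log(1 - E(T)). E and the accumulated integral are
solved jointly by an adaptive stiff-capable integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize

from .env import EnvCurve
from .selection import aic as _aic, aicc as _aicc

__all__ = [
    "RateFunction",
    "BDModelSpec",
    "FitResult",
    "bd_loglik",
    "fit_bd_family",
    "LikelihoodError",
    "TIME_FAMILY",
    "ENV_FAMILY",
]


class LikelihoodError(RuntimeError):
    """Non-finite likelihood / integrator failure; carries the parameter point."""


@dataclass
class RateFunction:
    """Speciation or extinction rate as a function of age (Ma)."""

    kind: str                     # constant | exp_time | exp_env
    rate0: float                  # events / lineage / Myr, >= 0
    alpha: float = 0.0            # sensitivity (per Myr, or per env unit)
    env: EnvCurve | None = None

    def __post_init__(self):
        if self.kind not in ("constant", "exp_time", "exp_env"):
            raise ValueError(f"unknown rate kind {self.kind!r}")
        if self.rate0 < 0:
            raise LikelihoodError(f"negative base rate {self.rate0}")
        if self.kind == "exp_env" and self.env is None:
            raise ValueError("exp_env rate requires an EnvCurve")

    def __call__(self, t):
        if self.kind == "constant":
            return self.rate0 * np.ones_like(np.asarray(t, dtype=float))
        if self.kind == "exp_time":
            return self.rate0 * np.exp(self.alpha * np.asarray(t, dtype=float))
        return self.rate0 * np.exp(self.alpha * self.env(t))


ZERO_RATE = RateFunction("constant", 0.0)


@dataclass
class BDModelSpec:
    lambda_fn: RateFunction
    mu_fn: RateFunction | None = None      # None -> pure birth
    sampling_fraction: float = 0.92
    conditioning: str = "crown_survival"   # crown_survival | none

    def __post_init__(self):
        if not (0.0 < self.sampling_fraction <= 1.0):
            raise ValueError("sampling fraction must be in (0, 1]")
        if self.conditioning not in ("crown_survival", "none"):
            raise ValueError(f"unknown conditioning {self.conditioning!r}")

    @property
    def mu(self) -> RateFunction:
        return self.mu_fn if self.mu_fn is not None else ZERO_RATE


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model; aic = 2k - 2 logL by construction."""

    label: str
    loglik: float
    params: dict
    n_params: int
    converged: bool = True
    n_starts_used: int = 1
    metadata: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return _aic(self.loglik, self.n_params)

    def aicc(self, n: int) -> float:
        return _aicc(self.loglik, self.n_params, n)


def bd_loglik(bt: np.ndarray, spec: BDModelSpec, rtol: float = 1e-9,
              atol: float = 1e-11) -> float:
    """Log-likelihood of branching times under a birth-death model.

    bt: internal-node ages, any order; the crown age is max(bt).
    """
    bt = np.sort(np.asarray(bt, dtype=float))[::-1]
    if bt.size < 1 or np.any(bt <= 0):
        raise ValueError("branching times must be positive")
    n = bt.size + 1
    T = bt[0]
    f = spec.sampling_fraction
    lam, mu = spec.lambda_fn, spec.mu

    if spec.lambda_fn.kind == "exp_env":
        lo, hi = spec.lambda_fn.env.age_range
        # curves clamp outside their range; just demand some overlap
        if T <= lo:
            raise ValueError("crown age below env curve range")

    def rhs(t, y):
        E = y[0]
        lt = float(lam(t))
        mt = float(mu(t))
        dE = mt - (lt + mt) * E + lt * E * E
        dG = 2.0 * lt * E - (lt + mt)
        return (dE, dG)

    ages_up = np.concatenate([[0.0], bt[::-1]])  # ascending, ends at T
    sol = solve_ivp(
        rhs, (0.0, T), [1.0 - f, 0.0], method="LSODA",
        t_eval=ages_up, rtol=rtol, atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise LikelihoodError(
            f"E-ODE failed for lambda0={lam.rate0}, mu0={mu.rate0}: {sol.message}"
        )
    E = sol.y[0]
    G = sol.y[1]
    # k(t) = n on [0, t_{n-1}], n-1 on the next interval, ..., 2 near the crown
    k = np.arange(n, 1, -1)
    ll = n * np.log(f)
    ll += float(np.sum(k * np.diff(G)))
    if n > 2:
        lam_nodes = np.asarray(lam(bt[1:]), dtype=float)
        if np.any(lam_nodes <= 0):
            raise LikelihoodError("speciation rate <= 0 at a branching time")
        ll += float(np.sum(np.log(lam_nodes)))
    if spec.conditioning == "crown_survival":
        surv = 1.0 - E[-1]
        if surv <= 0:
            raise LikelihoodError("survival probability underflow at the crown")
        ll -= 2.0 * np.log(surv)
    if not np.isfinite(ll):
        raise LikelihoodError(f"non-finite log-likelihood at {spec}")
    return float(ll)


# -- model families ----------------------------------------------------------

# (label, parameter names); parameters draw from {lambda0, alpha, mu0, beta}
TIME_FAMILY = [
    ("BCST", ("lambda0",)),                      # Yule
    ("BCST_DCST", ("lambda0", "mu0")),
    ("BVAR", ("lambda0", "alpha")),
    ("BVAR_DCST", ("lambda0", "alpha", "mu0")),
    ("BCST_DVAR", ("lambda0", "mu0", "beta")),
    ("BVAR_DVAR", ("lambda0", "alpha", "mu0", "beta")),
]

ENV_FAMILY = [
    ("BENV", ("lambda0", "alpha")),
    ("BENV_DCST", ("lambda0", "alpha", "mu0")),
    ("BCST_DENV", ("lambda0", "mu0", "beta")),
    ("BENV_DENV", ("lambda0", "alpha", "mu0", "beta")),
]

_BOUNDS = {"lambda0": (1e-6, 10.0), "mu0": (0.0, 10.0),
           "alpha": (-2.0, 2.0), "beta": (-2.0, 2.0)}


def _build_spec(label, names, values, family, envc, f, conditioning):
    p = dict(zip(names, values))
    var_kind = "exp_env" if family == "env" else "exp_time"
    if "alpha" in p:
        lam = RateFunction(var_kind, p["lambda0"], p["alpha"], envc)
    else:
        lam = RateFunction("constant", p["lambda0"])
    if "beta" in p:
        mu = RateFunction(var_kind, p["mu0"], p["beta"], envc)
    elif "mu0" in p:
        mu = RateFunction("constant", p["mu0"])
    else:
        mu = None
    return BDModelSpec(lam, mu, f, conditioning)


def _multi_start(objective, names, starts, polish=True):
    """Nelder-Mead from several starts, polished by bounded quasi-Newton."""
    bounds = [_BOUNDS[nm] for nm in names]
    best = None
    n_ok = 0
    for x0 in starts:
        try:
            res = minimize(objective, x0, method="Nelder-Mead", bounds=bounds,
                           options={"xatol": 1e-6, "fatol": 1e-8,
                                    "maxiter": 200 * len(x0)})
            if polish:
                res2 = minimize(objective, res.x, method="L-BFGS-B", bounds=bounds)
                if np.isfinite(res2.fun) and res2.fun <= res.fun:
                    res = res2
        except LikelihoodError:
            continue
        if not np.isfinite(res.fun) or res.fun >= 1e9:
            continue
        n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    return best, n_ok


def fit_bd_family(bt, family: str, env: EnvCurve | None = None,
                  f: float = 0.92, conditioning: str = "crown_survival",
                  n_starts: int = 3, seed: int = 0) -> list[FitResult]:
    """Fit the 6 time-dependent or 4 environment-dependent models by ML.

    Each model is fitted by bounded multi-start local optimization
    (Nelder-Mead polished by L-BFGS-B). Returns one FitResult per model;
    the best model is the converged one with lowest AIC.
    """
    bt = np.sort(np.asarray(bt, dtype=float))[::-1]
    if family == "time":
        models = TIME_FAMILY
    elif family == "env":
        if env is None:
            raise ValueError("family='env' requires an EnvCurve")
        models = ENV_FAMILY
    else:
        raise ValueError(f"unknown family {family!r}")

    n = bt.size + 1
    T = bt[0]
    lam_scale = max(np.log(n / 2.0) / T, 0.01)  # crude Yule-slope start
    rng = np.random.default_rng(seed)
    results = []
    for label, names in models:
        def objective(x, _names=names, _label=label):
            try:
                spec = _build_spec(_label, _names, x, family, env, f, conditioning)
                return -bd_loglik(bt, spec)
            except (LikelihoodError, ValueError):
                return 1e10

        base = {"lambda0": lam_scale, "mu0": 0.25 * lam_scale,
                "alpha": 0.0, "beta": 0.0}
        starts = []
        for i in range(n_starts):
            x0 = []
            for nm in names:
                v = base[nm]
                if i > 0:
                    lo, hi = _BOUNDS[nm]
                    v = v * np.exp(rng.normal(0, 0.7)) if nm in ("lambda0", "mu0") \
                        else v + rng.normal(0, 0.1)
                    v = np.clip(v, lo, hi)
                x0.append(v)
            starts.append(np.array(x0))
        best, n_ok = _multi_start(objective, names, starts)
        if best is None:
            results.append(FitResult(label, -np.inf, {}, len(names),
                                     converged=False, n_starts_used=0,
                                     metadata={"family": family}))
            continue
        params = dict(zip(names, map(float, best.x)))
        meta = {"family": family, "conditioning": conditioning, "f": f}
        if family == "env":
            meta["env_smooth_df"] = env.smooth_df
        results.append(FitResult(label, -float(best.fun), params, len(names),
                                 converged=True, n_starts_used=n_ok,
                                 metadata=meta))
    return results


def fit_results_table(results: list[FitResult]) -> pd.DataFrame:
    """Model-comparison CSV shape: model, np, logL, AIC, dAIC, wAIC, params."""
    from .selection import ModelRow, akaike_table

    ok = [r for r in results if r.converged]
    rows = [ModelRow(r.label, r.n_params, r.loglik, r.aic) for r in ok]
    table = akaike_table(rows)
    by_label = {r.label: r for r in ok}
    for pname in ("lambda0", "alpha", "mu0", "beta"):
        table[pname] = [by_label[m].params.get(pname, np.nan) for m in table["model"]]
    return table
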