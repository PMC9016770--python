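"""Episodic (piecewise-constant) birth-death models with tree-wide shifts.

Rates are parameterized per interval, present-to-past, as net diversification
r_i = lambda_i - mu_i and turnover eps_i = mu_i / lambda_i (the "Rate"/"Turn"
convention of the model-comparison tables), with shift times ST_i in Ma.

Within an interval the extinction-survival variable y = 1 - E obeys the
logistic equation dy/dt = r y - lambda y^2, so E and the per-lineage branch
factor Psi have closed forms; the likelihood below is the exact solution of
the segmented birth-death ODE. Shift count is chosen by sequential likelihood
ratio tests (3 df per added shift: one time, one rate, one turnover), with an
AIC table reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .bd import FitResult, LikelihoodError

__all__ = [
    "EpisodicModel",
    "episodic_loglik",
    "fit_shifts",
    "select_num_shifts",
    "rates_from_rt",
]


def rates_from_rt(r, eps):
    """(net diversification, turnover) -> (lambda, mu)."""
    r = np.asarray(r, dtype=float)
    eps = np.asarray(eps, dtype=float)
    lam = r / (1.0 - eps)
    return lam, lam * eps


@dataclass
class EpisodicModel:
    shift_times: np.ndarray       # ascending ages in (0, crown age), length s
    rates: np.ndarray             # r_i per interval, present-to-past, length s+1
    turnovers: np.ndarray         # eps_i in [0, 1), length s+1
    f: float = 0.92
    conditioning: str = "crown_survival"

    def __post_init__(self):
        self.shift_times = np.atleast_1d(np.asarray(self.shift_times, dtype=float))
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        self.turnovers = np.atleast_1d(np.asarray(self.turnovers, dtype=float))
        s = self.shift_times.size
        if self.rates.size != s + 1 or self.turnovers.size != s + 1:
            raise ValueError("need s+1 rates and turnovers for s shifts")
        if s and np.any(np.diff(self.shift_times) <= 0):
            raise ValueError("shift times must be strictly ascending")
        if np.any(self.turnovers < 0) or np.any(self.turnovers >= 1):
            raise ValueError("turnover must lie in [0, 1)")
        lam, _ = rates_from_rt(self.rates, self.turnovers)
        if np.any(lam <= 0):
            raise ValueError("lambda_i = r_i/(1-eps_i) must be positive")

    @property
    def n_shifts(self) -> int:
        return self.shift_times.size

    def interval_of(self, age) -> np.ndarray:
        """Index of the rate interval containing each age (boundary -> older)."""
        return np.searchsorted(self.shift_times, np.asarray(age, dtype=float),
                               side="left")


def episodic_loglik(bt, model: EpisodicModel) -> float:
    """Exact log-likelihood of branching times under piecewise-constant rates.

    y = 1 - E propagates in closed form across each rate interval, so the
    per-lineage branch factors and node terms are vectorized per interval.
    """
    asc = np.sort(np.asarray(bt, dtype=float))
    n = asc.size + 1
    T = asc[-1]
    st = model.shift_times
    if st.size and (st.min() <= 0 or st.max() >= T):
        raise ValueError("shift times must lie strictly inside (0, crown age)")
    lam_i, mu_i = rates_from_rt(model.rates, model.turnovers)

    edges = np.concatenate([[0.0], st, [T]])
    y = model.f
    ll = n * np.log(model.f)
    for i in range(edges.size - 1):
        lo, hi = edges[i], edges[i + 1]
        lam, mu = lam_i[i], mu_i[i]
        r = lam - mu
        inside = asc[(asc > lo) & (asc < hi)]
        pts = np.concatenate([[lo], inside, [hi]])
        dt = pts - lo
        if abs(r) > 1e-12:
            em1 = np.expm1(r * dt)
            y_pts = r * y * (em1 + 1.0) / (r + lam * y * em1)
        else:
            y_pts = y / (1.0 + lam * y * dt)
        k = n - np.searchsorted(asc, pts[:-1], side="right")
        logy = np.log(y_pts)
        seg = -r * np.diff(dt) + 2.0 * np.diff(logy)
        ll += float(k @ seg)
        # node terms: branching ages in (lo, hi], crown excluded
        n_nodes = inside.size + (1 if (hi < T and np.any(asc == hi)) else 0)
        if n_nodes:
            if lam <= 0:
                raise LikelihoodError("lambda <= 0 at a branching time")
            ll += n_nodes * np.log(lam)
        y = float(y_pts[-1])
    if model.conditioning == "crown_survival":
        if y <= 0:
            raise LikelihoodError("survival probability underflow")
        ll -= 2.0 * np.log(y)
    if not np.isfinite(ll):
        raise LikelihoodError(f"non-finite episodic loglik at {model}")
    return float(ll)


# -- fitting -----------------------------------------------------------------

_R_BOUNDS = (1e-6, 10.0)
_EPS_BOUNDS = (0.0, 0.999)


def _optimize_rates(bt, shift_times, f, conditioning, x0_list, coarse=False):
    """ML over (r_i, eps_i) with shift times held fixed.

    coarse=True uses a cheap Nelder-Mead budget (for grid scanning); the
    chosen placement is always re-polished at full precision.
    """
    s = len(shift_times)
    bounds = [_R_BOUNDS] * (s + 1) + [_EPS_BOUNDS] * (s + 1)

    def objective(x):
        try:
            m = EpisodicModel(np.asarray(shift_times), x[: s + 1], x[s + 1:],
                              f, conditioning)
            return -episodic_loglik(bt, m)
        except (ValueError, LikelihoodError):
            return 1e10

    opts = ({"xatol": 1e-3, "fatol": 1e-3, "maxiter": 120 * (s + 1)}
            if coarse else
            {"xatol": 1e-7, "fatol": 1e-8, "maxiter": 4000})
    best = None
    for x0 in x0_list:
        res = minimize(objective, x0, method="Nelder-Mead", bounds=bounds,
                       options=opts)
        if np.isfinite(res.fun) and res.fun < 1e9 and (best is None or res.fun < best.fun):
            best = res
    return best


def fit_shifts(bt, max_shifts: int = 4, grid_step: float = 0.1, f: float = 0.92,
               conditioning: str = "crown_survival", n_starts: int = 3,
               seed: int = 0) -> list[dict]:
    """Greedy grid search over shift placements for s = 0..max_shifts.

    Candidate shift times live on a grid of spacing grid_step Myr, excluding
    ages within grid_step of the present and of the crown age (boundary
    shifts are unidentifiable). Each new shift is optimized conditional on
    the previously accepted ones, with all rate parameters re-optimized.
    Shift times count as free parameters: np = 2(s+1) + s.
    """
    bt = np.sort(np.asarray(bt, dtype=float))[::-1]
    n = bt.size + 1
    T = bt[0]
    if max_shifts > 4:
        raise ValueError("max_shifts <= 4")
    grid = np.arange(grid_step, T - grid_step / 2, grid_step)
    grid = grid[(grid > grid_step * 0.999) & (grid < T - grid_step * 0.999)]
    rng = np.random.default_rng(seed)
    r_scale = max(np.log(n / 2.0) / T, 0.01)

    results: list[dict] = []
    # s = 0
    starts = [np.array([r_scale, e]) for e in (0.05, 0.5, 0.9)[:max(n_starts, 1)]]
    best = _optimize_rates(bt, [], f, conditioning, starts)
    if best is None:
        raise LikelihoodError("constant-rate episodic fit failed")
    prev_x, prev_ll = best.x, -best.fun
    prev_times: list[float] = []
    results.append(_pack(0, prev_times, prev_x, prev_ll, f))

    for s in range(1, max_shifts + 1):
        if bt.size < 3 * s + 2:
            break  # fewer branching times than parameters
        best_cand = None
        for g in grid:
            if any(abs(g - t) < grid_step / 2 for t in prev_times):
                continue
            times = sorted(prev_times + [float(g)])
            j = times.index(float(g))
            r0 = np.insert(prev_x[:s], j, prev_x[min(j, s - 1)])
            e0 = np.insert(prev_x[s:], j, prev_x[s + min(j, s - 1)])
            res = _optimize_rates(bt, times, f, conditioning,
                                  [np.concatenate([r0, e0])], coarse=True)
            if res is not None and (best_cand is None or res.fun < best_cand[0].fun):
                best_cand = (res, times)
        if best_cand is None:
            break
        res, times = best_cand
        # polish with extra jittered starts at the chosen placement
        extra = [res.x * np.exp(rng.normal(0, 0.3, res.x.size))
                 for _ in range(max(n_starts - 1, 0))]
        extra = [np.clip(x, 1e-6, 0.998) for x in extra]
        res2 = _optimize_rates(bt, times, f, conditioning, [res.x] + extra)
        if res2 is not None and res2.fun < res.fun:
            res = res2
        prev_x, prev_ll, prev_times = res.x, -res.fun, list(times)
        results.append(_pack(s, prev_times, prev_x, prev_ll, f))
    return results


def _pack(s, times, x, ll, f):
    r = np.asarray(x[: s + 1], dtype=float)
    eps = np.asarray(x[s + 1:], dtype=float)
    params = {}
    for i in range(s + 1):
        params[f"rate_{i + 1}"] = float(r[i])
        params[f"turn_{i + 1}"] = float(eps[i])
    for i, t in enumerate(times):
        params[f"ST_{i + 1}"] = float(t)
    fit = FitResult(
        label=f"BD-{s} shifts" if s else "BD-constant",
        loglik=float(ll), params=params, n_params=3 * s + 2,
        metadata={"f": f, "n_shifts": s},
    )
    return {"s": s, "shift_times": list(map(float, times)), "fit": fit}


def select_num_shifts(fits: list[dict], alpha: float = 0.05,
                      df_per_shift: int = 3) -> int:
    """Smallest s such that adding one more shift is not supported by LRT."""
    from .selection import lrt

    fits = sorted(fits, key=lambda d: d["s"])
    chosen = fits[0]["s"]
    for a, b in zip(fits[:-1], fits[1:]):
        ll0, ll1 = a["fit"].loglik, b["fit"].loglik
        _, p = lrt(min(ll0, ll1 + 1e-9), ll1, df_per_shift)
        if p < alpha and ll1 > ll0:
            chosen = b["s"]
        else:
            break
    return chosen
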