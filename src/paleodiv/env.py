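"""Paleoenvironmental proxy curves: smoothing-spline interpolation over age.

Curves are indexed by age in Ma before the present (matching the proxy
tables: temperature from d18O, CO2, d13C_organic, marine fossil diversity).
Queries outside the sampled age range clamp to the boundary values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate

__all__ = ["EnvCurve", "make_env_interpolator", "read_env_csv"]


@dataclass
class EnvCurve:
    ages: np.ndarray          # strictly increasing, Ma
    values: np.ndarray
    smooth_df: int            # effective degrees of freedom of the smoother
    _fn: object = field(repr=False, default=None)

    @property
    def age_range(self) -> tuple[float, float]:
        return float(self.ages[0]), float(self.ages[-1])

    def __call__(self, age):
        a = np.clip(np.asarray(age, dtype=float), self.ages[0], self.ages[-1])
        out = self._fn(a)
        return float(out) if np.isscalar(age) else np.asarray(out)


def make_env_interpolator(samples, smooth_df: int | None = None) -> EnvCurve:
    """Build a clamped cubic (smoothing) spline through (age, value) samples.

    smooth_df controls flexibility: with smooth_df >= n_samples the curve
    interpolates the samples exactly; smaller values fit a least-squares
    B-spline with smooth_df degrees of freedom. Default min(n_samples, 50).
    The df actually used is recorded on the curve so every fit can report it.
    """
    arr = np.asarray(list(samples), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (age, value) samples")
    order = np.argsort(arr[:, 0], kind="mergesort")
    ages, values = arr[order, 0], arr[order, 1]
    if np.any(np.diff(ages) <= 0):
        raise ValueError("duplicate or non-increasing ages in env samples")
    n = len(ages)
    if smooth_df is None:
        smooth_df = min(n, 50)
    smooth_df = int(smooth_df)
    k = min(3, n - 1)
    if smooth_df >= n or n <= 4:
        fn = interpolate.InterpolatedUnivariateSpline(ages, values, k=k)
        used_df = n
    else:
        # least-squares cubic B-spline with smooth_df degrees of freedom:
        # df = n_interior_knots + k + 1  ->  interior knots at quantile ages
        n_interior = max(smooth_df - (k + 1), 0)
        if n_interior == 0:
            coef = np.polyfit(ages, values, deg=min(k, smooth_df - 1))
            poly = np.poly1d(coef)
            fn = poly
        else:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            knots = np.quantile(ages, qs)
            knots = knots[(knots > ages[0]) & (knots < ages[-1])]
            fn = interpolate.LSQUnivariateSpline(ages, values, knots, k=k)
        used_df = smooth_df
    return EnvCurve(ages=ages, values=values, smooth_df=used_df, _fn=fn)


def read_env_csv(path, smooth_df: int | None = None) -> EnvCurve:
    """Read a proxy curve CSV with header columns age_Ma,value."""
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "age_ma" not in cols or "value" not in cols:
        raise ValueError(f"{path}: expected columns 'age_Ma,value', got {list(df.columns)}")
    return make_env_interpolator(
        np.column_stack([df[cols["age_ma"]], df[cols["value"]]]), smooth_df
    )
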