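"""AIC / AICc tables, Akaike weights and likelihood-ratio tests.

Shared by every fitting module; the CSV writer mirrors the layout of the
cross-framework model-comparison table (model, df, logL, AIC, dAIC, wAIC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["aic", "aicc", "akaike_table", "lrt", "ModelRow"]


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k - 2 logL."""
    return 2.0 * k - 2.0 * loglik


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; requires n > k + 1."""
    base = aic(loglik, k)
    denom = n - k - 1
    if denom <= 0:
        return np.inf
    return base + 2.0 * k * (k + 1) / denom


@dataclass
class ModelRow:
    label: str
    n_params: int
    loglik: float
    aic: float
    aicc: float = np.nan
    delta: float = field(default=np.nan)
    weight: float = field(default=np.nan)


def akaike_table(rows, use_aicc: bool = False) -> pd.DataFrame:
    """Rank models by (A)AIC; attach delta and Akaike weights.

    Equal-AIC ties are broken toward fewer parameters. Weights are reported
    both as fractions and percentages.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("empty model table")
    score = np.array([r.aicc if use_aicc else r.aic for r in rows], dtype=float)
    delta = score - score.min()
    w = np.exp(-0.5 * delta)
    w = w / w.sum()
    df = pd.DataFrame(
        {
            "model": [r.label for r in rows],
            "np": [r.n_params for r in rows],
            "logL": [r.loglik for r in rows],
            "AIC": [r.aic for r in rows],
            "AICc": [r.aicc for r in rows],
            "dAIC": delta,
            "wAIC": w,
            "wAIC_pct": 100.0 * w,
        }
    )
    df = df.sort_values(["dAIC", "np"], kind="mergesort").reset_index(drop=True)
    return df


def lrt(loglik0: float, loglik1: float, df: int) -> tuple[float, float]:
    """Likelihood-ratio test of nested models (model 1 nests model 0).

    Returns (chi-square statistic, p-value). Small negative statistics from
    optimizer noise are clamped to zero; large ones are an error.
    """
    chi2 = 2.0 * (loglik1 - loglik0)
    if chi2 < -1e-6:
        raise ValueError(
            f"negative LRT statistic {chi2:.4g}: models not nested or fit failed"
        )
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, p
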