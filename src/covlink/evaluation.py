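"""Model-fit metrics and coverage comparisons.

Three fit metrics are used: the coefficient of determination (computed as
1 - SS_res/SS_tot about the observed mean, so it can be negative for a model
worse than the mean), Pearson's correlation, and the RMSE. Correlations
above 0.8 count as strong, 0.5-0.8 as moderate, below 0.5 as weak.

Also here: the arithmetic for comparing coverage estimates against default
proxies (differences in percentage points) and relative impact ratios for
scale-up scenarios (updated vs current lives saved).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Tuple

import numpy as np
import pandas as pd

__all__ = [
    "EvalMetrics",
    "compute_metrics",
    "classify_correlation",
    "compare_to_proxy",
    "impact_ratio",
    "relative_difference",
]


@dataclass(frozen=True)
class EvalMetrics:
    r_squared: float
    pearson_rho: float  # NaN when undefined (constant observed vector)
    rmse: float
    n: int


def _round_half_up(value: float, digits: int = 0) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def compute_metrics(observed, predicted) -> EvalMetrics:
    """R², Pearson's rho and RMSE of predictions against observations.

    With a constant observed vector the correlation (and R²) are undefined
    and returned as NaN — flagged, not silently zero.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must have equal length >= 2")
    if np.any(~np.isfinite(obs)) or np.any(~np.isfinite(pred)):
        raise ValueError("missing or non-finite values are not allowed")
    resid = obs - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return EvalMetrics(r_squared=math.nan, pearson_rho=math.nan, rmse=rmse, n=obs.size)
    r_squared = 1.0 - float(np.sum(resid**2)) / ss_tot
    if np.std(pred) == 0.0:
        rho = math.nan
    else:
        rho = float(np.corrcoef(obs, pred)[0, 1])
    return EvalMetrics(r_squared=r_squared, pearson_rho=rho, rmse=rmse, n=obs.size)


def classify_correlation(rho: float) -> str:
    """Strength category for a correlation: strong (>0.8), moderate
    (0.5-0.8 inclusive), weak (<0.5)."""
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {rho}")
    if rho > 0.8:
        return "strong"
    if rho >= 0.5:
        return "moderate"
    return "weak"


def compare_to_proxy(estimates: pd.Series, proxies: pd.Series) -> Tuple[pd.DataFrame, dict]:
    """Differences (proxy - estimate) in percentage points, keyed alike.

    Both inputs are proportions on [0, 1] indexed by matching
    (country, intervention)-style keys; mismatched keys raise.
    """
    if not estimates.index.equals(proxies.index):
        if set(estimates.index) != set(proxies.index):
            raise ValueError("estimates and proxies must share the same keys")
        proxies = proxies.reindex(estimates.index)
    diff = (proxies - estimates) * 100.0
    table = pd.DataFrame(
        {
            "estimate": estimates,
            "proxy": proxies,
            "difference_pp": diff,
        }
    )
    summary = {
        "min_difference_pp": float(diff.min()),
        "max_difference_pp": float(diff.max()),
    }
    return table, summary


def impact_ratio(updated_impact: float, current_impact: float) -> Tuple[int, float]:
    """Updated impact as a percent of current impact.

    Returns ``(rounded, unrounded)`` where ``rounded`` is the nearest
    integer percent (half-up) and ``unrounded`` the full-precision value.
    """
    if current_impact <= 0:
        raise ValueError("current_impact must be positive")
    value = 100.0 * updated_impact / current_impact
    return int(_round_half_up(value)), value


def relative_difference(current: float, updated: float, digits: int = 1) -> Tuple[float, float]:
    """Relative difference 100*(current - updated)/current, in percent.

    Returns ``(rounded, unrounded)``, rounded half-up to ``digits``.
    """
    if current <= 0:
        raise ValueError("current must be positive")
    value = 100.0 * (current - updated) / current
    return _round_half_up(value, digits), value
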