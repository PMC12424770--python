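"""Variable transforms: Tukey ladder of powers, min-max scaling, Grubbs' test.

Comparative trait and count data here are strongly right-skewed (retroelement
counts in particular contain many zeros). Each response and predictor is
power-transformed along Tukey's ladder before regression, choosing the power
that maximises Shapiro-Wilk normality of the transformed values; predictors
are then min-max scaled to [0, 1] so effect sizes are comparable across
models. Grubbs' test flags single extreme values but flagged points are
reported, never auto-removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TukeyResult",
    "GrubbsResult",
    "default_ladder_grid",
    "tukey_transform",
    "minmax_normalize",
    "grubbs_test",
]


@dataclass(frozen=True)
class TukeyResult:
    lambda_t: float  # chosen ladder power
    transformed: np.ndarray
    normality_w: float  # Shapiro-Wilk W of the transformed values


@dataclass(frozen=True)
class GrubbsResult:
    g: float
    critical: float
    outlier_index: Optional[int]  # None when no point exceeds the critical value


def default_ladder_grid(step: float = 0.025, lo: float = -2.0, hi: float = 2.0) -> np.ndarray:
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def _apply_power(x: np.ndarray, p: float) -> np.ndarray:
    # sign flip for negative powers keeps the transform order-preserving
    if p > 0:
        return np.power(x, p)
    if p == 0:
        return np.log(x)
    return -np.power(x, p)


def tukey_transform(x: Sequence[float], grid: Optional[np.ndarray] = None) -> TukeyResult:
    """Pick the ladder power maximising Shapiro-Wilk W of the transformed data.

    The transform is ``x**p`` for p > 0, ``log(x)`` for p = 0, and ``-(x**p)``
    for p < 0 (sign flip preserves rank order). Powers requiring positivity
    (p <= 0, and fractional p on non-positive data) are skipped when the data
    contain zeros or negatives; if no candidate is valid a ``ValueError`` is
    raised.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("tukey_transform needs at least 3 values")
    if np.ptp(x) == 0:
        raise ValueError("tukey_transform: constant vector")
    grid = default_ladder_grid() if grid is None else np.asarray(grid, dtype=float)
    xmin = x.min()
    best: Optional[TukeyResult] = None
    for p in grid:
        if p <= 0 and xmin <= 0:
            continue
        if xmin < 0:
            continue  # fractional powers of negatives are undefined
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            t = _apply_power(x, float(p))
        if not np.all(np.isfinite(t)) or np.ptp(t) == 0:
            continue
        w = float(stats.shapiro(t).statistic)
        if best is None or w > best.normality_w:
            best = TukeyResult(lambda_t=float(p), transformed=t, normality_w=w)
    if best is None:
        raise ValueError("tukey_transform: no valid ladder power for these data")
    return best


def minmax_normalize(x: Sequence[float]) -> np.ndarray:
    """Affine map onto [0, 1]: min -> 0, max -> 1. Errors on constant input."""
    x = np.asarray(x, dtype=float)
    span = np.ptp(x)
    if span == 0:
        raise ValueError("minmax_normalize: constant vector")
    return (x - x.min()) / span


def grubbs_test(x: Sequence[float], alpha: float = 0.05) -> GrubbsResult:
    """Two-sided Grubbs' test for a single outlier.

    G = max |x_i - mean| / s with the n-1 sample standard deviation; the
    critical value is ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with t the
    upper alpha/(2n) quantile of Student's t on n-2 df. The maximal-deviation
    index is flagged iff G exceeds the critical value; callers decide whether
    to act on the flag (biologically meaningful extremes are typically kept).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("grubbs_test needs at least 3 values")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("grubbs_test: zero standard deviation")
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / s)
    t = stats.t.isf(alpha / (2 * n), n - 2)
    critical = float((n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2)))
    return GrubbsResult(g=g, critical=critical, outlier_index=idx if g > critical else None)
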