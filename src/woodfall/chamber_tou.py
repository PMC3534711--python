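"""Total oxygen uptake (TOU) from benthic-chamber O₂ time series.

The chamber encloses a known sediment area under a column of bottom water
of known height; TOU follows from the initial linear decrease of the O₂
concentration in the enclosed water.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class ChamberTimeSeries:
    """O₂ (µM) versus time (h since chamber closure)."""

    time_h: np.ndarray
    O2_uM: np.ndarray
    water_height_m: float
    chamber_area_cm2: float = 284.0

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.O2_uM = np.asarray(self.O2_uM, dtype=float)
        if self.time_h.shape != self.O2_uM.shape or self.time_h.ndim != 1:
            raise ValueError("time and O2 must be 1-D arrays of equal length")
        if len(self.time_h) and np.any(np.diff(self.time_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.water_height_m <= 0:
            raise ValueError("water height must be positive")
        if self.chamber_area_cm2 <= 0:
            raise ValueError("chamber area must be positive")


@dataclass
class DeclineFit:
    slope_uM_per_h: float
    intercept_uM: float
    r2: float
    n_points: int
    window_h: tuple[float, float]
    fallback: bool = False  # no prefix met the R² threshold


def _linfit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line fit returning (slope, intercept, R²)."""
    tm, ym = t.mean(), y.mean()
    dt = t - tm
    denom = np.dot(dt, dt)
    slope = np.dot(dt, y - ym) / denom
    intercept = ym - slope * tm
    resid = y - (slope * t + intercept)
    ss_tot = np.dot(y - ym, y - ym)
    r2 = 1.0 - np.dot(resid, resid) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def fit_initial_decline(
    series: ChamberTimeSeries, min_points: int = 10, r2_min: float = 0.98
) -> DeclineFit:
    """Fit the initial linear O₂ decline.

    Returns the fit over the longest prefix window (starting at the first
    sample) whose least-squares fit reaches R² ≥ r2_min.  If no prefix of
    at least ``min_points`` qualifies, falls back to the first
    ``min_points`` samples with a warning.
    """
    t, y = series.time_h, series.O2_uM
    n = len(t)
    if n < min_points:
        raise ValueError(f"need >= {min_points} samples, have {n}")
    best: DeclineFit | None = None
    for m in range(min_points, n + 1):
        slope, intercept, r2 = _linfit(t[:m], y[:m])
        if r2 >= r2_min:
            best = DeclineFit(slope, intercept, r2, m, (float(t[0]), float(t[m - 1])))
    if best is None:
        warnings.warn(
            f"no prefix window reached R^2 >= {r2_min}; "
            f"falling back to the first {min_points} samples",
            stacklevel=2,
        )
        slope, intercept, r2 = _linfit(t[:min_points], y[:min_points])
        best = DeclineFit(
            slope, intercept, r2, min_points,
            (float(t[0]), float(t[min_points - 1])), fallback=True,
        )
    return best


def tou_from_slope(slope_uM_per_h: float, water_height_m: float) -> tuple[float, bool]:
    """Convert an O₂ slope to TOU in mmol m⁻² d⁻¹.

    TOU = −slope × height × 24 (µM ≡ mmol m⁻³).  A positive slope (O₂
    increase) yields a negative TOU with the efflux flag set.
    """
    if water_height_m <= 0:
        raise ValueError("water height must be positive")
    tou = -slope_uM_per_h * water_height_m * 24.0
    return tou, tou < 0


def total_oxygen_uptake(
    series: ChamberTimeSeries, min_points: int = 10, r2_min: float = 0.98
) -> tuple[float, DeclineFit]:
    """TOU from a chamber series: initial-decline fit, then slope → flux."""
    fit = fit_initial_decline(series, min_points=min_points, r2_min=r2_min)
    tou, _ = tou_from_slope(fit.slope_uM_per_h, series.water_height_m)
    return tou, fit
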