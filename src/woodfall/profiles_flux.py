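"""Microsensor profile processing.

Converts concentration-vs-depth profiles into speciated sulfide, steepest
porewater gradients, Fick's-law diffusive fluxes, oxygen penetration depth
and depth-integrated inventories.

Unit conventions (package-wide): concentrations in µM, depths in mm
(positive downward, interface at 0), diffusion coefficients in m² s⁻¹,
fluxes in mmol m⁻² d⁻¹.  A gradient of 1 µM mm⁻¹ equals 1 mol m⁻⁴, so the
flux conversion factor from φ·D·(dc/dz) [mol m⁻² s⁻¹] to mmol m⁻² d⁻¹ is
86400 × 1000.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: mol m⁻² s⁻¹ → mmol m⁻² d⁻¹
FLUX_TO_MMOL_M2_D = 86_400.0 * 1_000.0

VALID_ANALYTES = ("O2", "H2S", "pH", "DOC", "totalS")


@dataclass
class ConcentrationProfile:
    """An analyte profile over sediment depth.

    depth_mm is strictly increasing, positive downward, 0 at the interface;
    points above the interface (boundary layer) carry negative depths.
    """

    analyte: str
    depth_mm: np.ndarray
    value: np.ndarray
    porosity: float = 1.0
    temperature_C: float | None = None
    salinity_PSU: float | None = None

    def __post_init__(self) -> None:
        self.depth_mm = np.asarray(self.depth_mm, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.analyte not in VALID_ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}")
        if self.depth_mm.shape != self.value.shape or self.depth_mm.ndim != 1:
            raise ValueError("depth and value must be 1-D arrays of equal length")
        if len(self.depth_mm) and np.any(np.diff(self.depth_mm) <= 0):
            raise ValueError("depths must be strictly increasing")
        if not 0.0 < self.porosity <= 1.0:
            raise ValueError(f"porosity must be in (0, 1], got {self.porosity}")

    def below_interface(self) -> "ConcentrationProfile":
        """Sub-interface part of the profile (depth ≥ 0)."""
        keep = self.depth_mm >= 0.0
        return ConcentrationProfile(
            self.analyte,
            self.depth_mm[keep],
            self.value[keep],
            self.porosity,
            self.temperature_C,
            self.salinity_PSU,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"depth_mm": self.depth_mm, "value": self.value})


@dataclass
class GradientResult:
    gradient_uM_per_mm: float
    window_mm: tuple[float, float]
    degenerate: bool = False


@dataclass
class FluxResult:
    """A diffusive flux with the parameters that produced it."""

    analyte: str
    J_diff_mmol_m2_d: float
    gradient_uM_per_mm: float
    window_mm: tuple[float, float]
    D_sed_m2_s: float
    porosity: float
    note: str = ""


@dataclass
class SulfideSpeciation:
    H2S_measured_uM: float
    pH: float
    pK1: float

    @property
    def total_sulfide_uM(self) -> float:
        return self.H2S_measured_uM * (1.0 + 10.0 ** (self.pH - self.pK1))


def speciate_sulfide(
    h2s_profile: ConcentrationProfile,
    ph_profile: ConcentrationProfile,
    pK1: float,
) -> ConcentrationProfile:
    """Convert measured H₂S to total sulfide (H₂S + HS⁻) using pH and pK1.

    ΣH₂S = [H₂S] · (1 + 10^(pH − pK1)); the S²⁻ contribution is neglected
    (pK2 far above seawater pH).  The pH profile is linearly interpolated
    onto the H₂S depth grid; H₂S depths outside the pH grid are dropped
    with a warning.
    """
    if pK1 <= 0:
        raise ValueError("pK1 must be positive")
    if h2s_profile.analyte != "H2S" or ph_profile.analyte != "pH":
        raise ValueError("expected an H2S profile and a pH profile")
    depth = h2s_profile.depth_mm
    lo, hi = ph_profile.depth_mm[0], ph_profile.depth_mm[-1]
    inside = (depth >= lo) & (depth <= hi)
    if not np.any(inside):
        raise ValueError("H2S and pH depth grids do not overlap")
    if not np.all(inside):
        warnings.warn(
            f"dropping {int(np.sum(~inside))} H2S depths outside the pH grid",
            stacklevel=2,
        )
    depth = depth[inside]
    h2s = h2s_profile.value[inside]
    ph = np.interp(depth, ph_profile.depth_mm, ph_profile.value)
    total = h2s * (1.0 + 10.0 ** (ph - pK1))
    return ConcentrationProfile(
        "totalS",
        depth,
        total,
        h2s_profile.porosity,
        h2s_profile.temperature_C,
        h2s_profile.salinity_PSU,
    )


def _window_slopes(depth: np.ndarray, value: np.ndarray, k: int) -> np.ndarray:
    """Least-squares slope of every length-k sliding window."""
    n = len(depth)
    slopes = np.empty(n - k + 1)
    for i in range(n - k + 1):
        x = depth[i : i + k]
        y = value[i : i + k]
        xm = x - x.mean()
        denom = np.dot(xm, xm)
        slopes[i] = np.dot(xm, y) / denom if denom > 0 else 0.0
    return slopes


def steepest_gradient(
    profile: ConcentrationProfile,
    window_pts: int = 3,
    direction: str = "both",
) -> GradientResult:
    """Steepest least-squares gradient over a sliding window.

    Only sub-interface points (depth ≥ 0) are searched, excluding the
    diffusive boundary layer.  ``direction`` restricts the sign of the
    candidate slopes: "down" keeps negative (concentration decreasing with
    depth), "up" keeps positive, "both" keeps all.  Ties break toward the
    shallower window.
    """
    if window_pts < 2:
        raise ValueError("window_pts must be >= 2")
    sub = profile.below_interface()
    depth, value = sub.depth_mm, sub.value
    if len(depth) < window_pts:
        raise ValueError(
            f"need >= {window_pts} sub-interface points, have {len(depth)}"
        )
    slopes = _window_slopes(depth, value, window_pts)
    if direction == "down":
        candidate = np.where(slopes < 0, -slopes, -np.inf)
    elif direction == "up":
        candidate = np.where(slopes > 0, slopes, -np.inf)
    elif direction == "both":
        candidate = np.abs(slopes)
    else:
        raise ValueError(f"direction must be up/down/both, not {direction!r}")
    if np.all(np.isinf(candidate) & (candidate < 0)):
        return GradientResult(0.0, (float(depth[0]), float(depth[window_pts - 1])), True)
    # shallowest window within float tolerance of the maximum
    top = np.max(candidate)
    tol = max(1e-12, 1e-9 * abs(top))
    best = int(np.nonzero(candidate >= top - tol)[0][0])
    grad = float(slopes[best])
    window = (float(depth[best]), float(depth[best + window_pts - 1]))
    return GradientResult(grad, window, degenerate=(grad == 0.0))


def fick_flux(
    gradient: GradientResult | float,
    porosity: float,
    D_sed: float,
    analyte: str = "O2",
) -> FluxResult:
    """Diffusive flux J = φ · D_sed · dc/dz in mmol m⁻² d⁻¹.

    The gradient is given in µM mm⁻¹, numerically equal to mol m⁻⁴.
    """
    if not 0.0 < porosity <= 1.0:
        raise ValueError(f"porosity must be in (0, 1], got {porosity}")
    if D_sed <= 0:
        raise ValueError(f"D_sed must be positive, got {D_sed}")
    if isinstance(gradient, GradientResult):
        grad = gradient.gradient_uM_per_mm
        window = gradient.window_mm
    else:
        grad = float(gradient)
        window = (np.nan, np.nan)
    J = porosity * D_sed * grad * FLUX_TO_MMOL_M2_D
    return FluxResult(analyte, J, grad, window, D_sed, porosity)


def sulfide_flux_total(
    totalS_profile: ConcentrationProfile,
    porosity: float,
    D_sed: float,
    window_pts: int = 3,
) -> FluxResult:
    """Total sulfide flux: |J_up| + |J_down| around the concentration peak.

    For a profile with an interior maximum the upward (negative) and
    downward (positive) steepest gradients bracket the peak and their flux
    magnitudes are summed.  Monotone profiles yield the single flux,
    flagged in ``note``.
    """
    up = steepest_gradient(totalS_profile, window_pts, direction="down")
    down = steepest_gradient(totalS_profile, window_pts, direction="up")
    J_up = fick_flux(up, porosity, D_sed, totalS_profile.analyte)
    J_down = fick_flux(down, porosity, D_sed, totalS_profile.analyte)
    if up.degenerate and down.degenerate:
        return FluxResult(
            totalS_profile.analyte, 0.0, 0.0, up.window_mm, D_sed, porosity,
            note="flat profile",
        )
    if up.degenerate or down.degenerate:
        single = J_down if up.degenerate else J_up
        return FluxResult(
            totalS_profile.analyte,
            abs(single.J_diff_mmol_m2_d),
            single.gradient_uM_per_mm,
            single.window_mm,
            D_sed,
            porosity,
            note="monotone profile: single flux",
        )
    total = abs(J_up.J_diff_mmol_m2_d) + abs(J_down.J_diff_mmol_m2_d)
    return FluxResult(
        totalS_profile.analyte,
        total,
        np.nan,
        (up.window_mm[0], down.window_mm[1]),
        D_sed,
        porosity,
        note="sum of steepest upward and downward fluxes",
    )


@dataclass
class PenetrationDepth:
    depth_mm: float
    open_bound: bool = False  # True → analyte never fell below the limit

    def __str__(self) -> str:
        return f">{self.depth_mm:g}" if self.open_bound else f"{self.depth_mm:g}"


def oxygen_penetration_depth(
    o2_profile: ConcentrationProfile, detection_limit_uM: float = 1.0
) -> PenetrationDepth:
    """Depth (mm) of the first crossing below the detection limit.

    Linearly interpolates between the bracketing samples; a profile that
    never crosses returns an open bound at its deepest depth.
    """
    sub = o2_profile.below_interface()
    depth, value = sub.depth_mm, sub.value
    if len(depth) == 0:
        raise ValueError("no sub-interface points")
    if value[0] <= detection_limit_uM:
        warnings.warn("surface value already at/below detection limit", stacklevel=2)
        return PenetrationDepth(0.0)
    below = np.nonzero(value < detection_limit_uM)[0]
    if len(below) == 0:
        return PenetrationDepth(float(depth[-1]), open_bound=True)
    i = below[0]
    z = np.interp(detection_limit_uM, [value[i], value[i - 1]], [depth[i], depth[i - 1]])
    return PenetrationDepth(float(z))


def integrate_depth(
    layer_values: np.ndarray,
    layer_depths_cm: np.ndarray | None = None,
    depth_range_cm: tuple[float, float] | None = None,
    layer_thickness_cm: float = 1.0,
    to_mmol_m2: bool = False,
) -> float:
    """Depth integral of per-layer values over contiguous layers.

    ``layer_values`` are per-volume quantities (cells cm⁻³ or
    nmol cm⁻³ d⁻¹) for consecutive layers of ``layer_thickness_cm``;
    ``layer_depths_cm`` gives each layer's top depth.  NaN layers inside
    the range are filled by linear interpolation from their neighbours.
    With ``to_mmol_m2`` the result (assumed nmol cm⁻²) is converted to
    mmol m⁻² (× 10⁴ cm² m⁻² × 10⁻⁶ mmol nmol⁻¹ = × 0.01).
    """
    values = np.asarray(layer_values, dtype=float)
    if layer_depths_cm is None:
        depths = np.arange(len(values)) * layer_thickness_cm
    else:
        depths = np.asarray(layer_depths_cm, dtype=float)
    if depth_range_cm is not None:
        lo, hi = depth_range_cm
        keep = (depths >= lo) & (depths < hi)
        values, depths = values[keep], depths[keep]
    if len(values) == 0:
        raise ValueError("empty depth range")
    if np.any(np.isnan(values)):
        good = ~np.isnan(values)
        if not np.any(good):
            raise ValueError("all layers missing")
        warnings.warn("interpolating missing layers", stacklevel=2)
        values = np.interp(depths, depths[good], values[good])
    total = float(np.sum(values) * layer_thickness_cm)
    return total * 0.01 if to_mmol_m2 else total
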