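"""Micropipette spring-constant calibration.

A pulled glass micropipette acts as a cantilever spring: a force ``F`` applied
at the tip produces a lateral deflection ``d`` with ``F = k d``.  The spring
constant ``k`` (μN μm⁻¹) is determined empirically, either by hanging water
droplets of known weight from the tip (droplet method) or by pressing the
pipette against a second, already-calibrated pipette and comparing deflections
(two-pipette method).  Typical pipettes span k = 0.04–1.17 μN μm⁻¹ with
uncertainties of order ≤ 0.01 μN μm⁻¹.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "PipetteCalibration",
    "droplet_weight",
    "fit_droplet_calibration",
    "fit_force_deflection",
    "two_pipette_k",
    "fit_two_pipette_series",
]

#: density of water, kg m^-3
WATER_DENSITY = 1000.0
#: standard gravity, m s^-2
STANDARD_GRAVITY = 9.81


@dataclass
class PipetteCalibration:
    """Fitted spring constant of one micropipette.

    k and sigma_k in μN μm⁻¹; residual_sd is the RMS force residual of the
    fit expressed as an equivalent deflection in μm (residual force / k).
    """

    k: float
    sigma_k: float
    method: str  # "droplet" | "two_pipette"
    n_points: int
    residual_sd: float

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"spring constant must be positive, got {self.k}")
        if self.sigma_k < 0:
            raise ValueError("sigma_k must be non-negative")
        if self.n_points < 2:
            raise ValueError("calibration needs at least 2 points")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PipetteCalibration":
        with open(path) as fh:
            return cls(**json.load(fh))


def droplet_weight(radius_um: float, rho: float = WATER_DENSITY,
                   g: float = STANDARD_GRAVITY) -> float:
    """Weight (μN) of a spherical water droplet of the given radius (μm).

    F = ρ g (4/3) π r³, evaluated in SI and returned in μN.  A 288 μm
    droplet of water weighs ≈ 0.98 μN — the scale of forces these pipettes
    are built to resolve.
    """
    radius_um = float(radius_um)
    if radius_um < 0:
        raise ValueError("droplet radius must be non-negative")
    r_m = radius_um * 1e-6
    return rho * g * (4.0 / 3.0) * math.pi * r_m**3 * 1e6


def _origin_slope_fit(x: np.ndarray, y: np.ndarray, free_intercept: bool):
    """Least-squares slope of y on x, through the origin by default.

    Returns (slope, slope standard error, residual array).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if free_intercept:
        A = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        dof = n - 2
        sxx = np.sum((x - x.mean()) ** 2)
    else:
        sxx = float(np.sum(x * x))
        if sxx == 0.0:
            raise ValueError("all abscissae are zero; cannot fit a slope")
        coef = np.array([np.sum(x * y) / sxx])
        resid = y - coef[0] * x
        dof = n - 1
    if dof > 0 and sxx > 0:
        se = math.sqrt(float(np.sum(resid**2)) / dof / sxx)
    else:
        se = 0.0
    return float(coef[0]), se, resid


def fit_force_deflection(forces_uN, deflections_um, *, method: str = "droplet",
                         free_intercept: bool = False) -> PipetteCalibration:
    """Fit k from paired (force, deflection) measurements.

    The physical model F = k d has no offset, so the regression is through
    the origin unless ``free_intercept`` is requested for diagnostics.
    """
    F = np.asarray(forces_uN, dtype=float)
    d = np.asarray(deflections_um, dtype=float)
    if len(F) != len(d):
        raise ValueError("forces and deflections must have equal length")
    if len(F) < 2:
        raise ValueError("need at least 2 calibration points to fit a slope")
    if np.any(d <= 0):
        raise ValueError("deflections must be positive")
    if np.ptp(d) == 0 and np.ptp(F) != 0:
        raise ValueError("all deflections identical with differing weights; "
                         "the series does not determine a slope")
    k, se, resid = _origin_slope_fit(d, F, free_intercept)
    if not k > 0:
        raise ValueError(f"fitted spring constant is non-positive ({k:.3g}); "
                         "check the calibration series")
    residual_sd = float(np.sqrt(np.mean(resid**2))) / k
    return PipetteCalibration(k=k, sigma_k=se, method=method,
                              n_points=len(F), residual_sd=residual_sd)


def fit_droplet_calibration(radii_um, deflections_um, *, rho: float = WATER_DENSITY,
                            g: float = STANDARD_GRAVITY,
                            free_intercept: bool = False) -> PipetteCalibration:
    """Calibrate from a series of hanging droplets.

    Each droplet's weight is computed from its imaged radius (sphere of
    water), and k is the through-origin slope of weight vs deflection.
    """
    radii_um = np.asarray(radii_um, dtype=float)
    if np.any(radii_um <= 0):
        raise ValueError("droplet radii must be positive")
    forces = np.array([droplet_weight(r, rho, g) for r in radii_um])
    return fit_force_deflection(forces, deflections_um, method="droplet",
                                free_intercept=free_intercept)


def two_pipette_k(k_ref: float, d_ref: float, d_unknown: float) -> float:
    """Spring constant from one quasi-static press against a reference pipette.

    The tips exert equal and opposite forces, so k_ref·d_ref = k·d_unknown.
    """
    if k_ref <= 0 or d_ref <= 0:
        raise ValueError("reference spring constant and deflection must be positive")
    if d_unknown <= 0:
        raise ValueError("unknown-pipette deflection must be positive "
                         "(zero deflection implies unphysical infinite stiffness)")
    return k_ref * d_ref / d_unknown


def fit_two_pipette_series(k_ref: float, d_ref_series, d_unknown_series,
                           *, free_intercept: bool = False) -> PipetteCalibration:
    """Ensemble two-pipette calibration over a pressing series.

    Fits the slope of reference force (k_ref·d_ref) against the unknown
    pipette's deflection.
    """
    d_ref = np.asarray(d_ref_series, dtype=float)
    if k_ref <= 0:
        raise ValueError("reference spring constant must be positive")
    if np.any(d_ref <= 0):
        raise ValueError("reference deflections must be positive")
    forces = k_ref * d_ref
    return fit_force_deflection(forces, d_unknown_series, method="two_pipette",
                                free_intercept=free_intercept)


def read_calibration_csv(path) -> pd.DataFrame:
    """Read a calibration series CSV with (radius_um | force_uN, deflection_um)."""
    df = pd.read_csv(path)
    if "deflection_um" not in df.columns:
        raise ValueError(f"calibration CSV missing 'deflection_um' in {path}")
    if "radius_um" not in df.columns and "force_uN" not in df.columns:
        raise ValueError(f"calibration CSV needs 'radius_um' or 'force_uN' in {path}")
    return df


def calibrate_from_csv(path, **kwargs) -> PipetteCalibration:
    df = read_calibration_csv(path)
    if "force_uN" in df.columns:
        return fit_force_deflection(df["force_uN"], df["deflection_um"], **kwargs)
    return fit_droplet_calibration(df["radius_um"], df["deflection_um"], **kwargs)
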