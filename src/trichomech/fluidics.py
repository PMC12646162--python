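"""Fluid-dynamics characterization of glandular fluid release.

On rupture the gland fluid emerges as a droplet over ~10 μm and ~1 ms
scales.  Whether it jets, sprays or merely spreads is governed by three
dimensionless groups built from the characteristic density ρ, surface
tension σ, viscosity μ, velocity U, length L and gravity g:

    Re = ρUL/μ   (inertia / viscosity)
    We = ρU²L/σ  (inertia / capillarity)
    Bo = ρgL²/σ  (gravity / capillarity)

All three come out far below unity for the observed scales, placing the
release in a capillarity-dominated regime (droplet spreading, no jetting).
Fluid properties were not directly measurable on nanolitre samples, so water
values serve as bounds: σ of water as an upper bound, ρ of water as a lower
bound.  Viscosity is estimated separately from capillary imbibition into the
glass micropipette via the Lucas–Washburn relation l²(t) = (σ r cosθ_c/2μ)·t.

This module works in SI units (m, s, kg), unlike the μm-based mechanics
modules; converters are provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FluidScales",
    "DimensionlessNumbers",
    "characteristic_velocity",
    "dimensionless_numbers",
    "viscosity_from_capillary",
    "um_to_m",
    "WATER_DENSITY_SI",
    "WATER_SURFACE_TENSION",
]

WATER_DENSITY_SI = 1000.0       # kg m^-3, lower bound for the gland fluid
WATER_SURFACE_TENSION = 0.072   # N m^-1, upper bound for the gland fluid
STANDARD_GRAVITY_SI = 9.81      # m s^-2


def um_to_m(value_um: float) -> float:
    """Convert micrometres (mechanics-module unit) to metres (this module)."""
    return value_um * 1e-6


@dataclass
class FluidScales:
    """Characteristic scales of the released fluid, SI units."""

    rho: float = WATER_DENSITY_SI       # kg m^-3
    sigma_surface: float = WATER_SURFACE_TENSION  # N m^-1
    mu: float = 0.1                     # Pa·s (lower edge of the measured band)
    U: float = 1e-2                     # m s^-1
    L_c: float = 1e-5                   # m (≈ gland cavity radius, 10 μm)
    tau_c: float = 1e-3                 # s (fluid emergence time scale)
    g: float = STANDARD_GRAVITY_SI      # m s^-2

    def __post_init__(self) -> None:
        for name in ("rho", "sigma_surface", "mu", "U", "L_c", "tau_c", "g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class DimensionlessNumbers:
    Re: float
    We: float
    Bo: float
    orders: dict = field(default_factory=dict)  # floor(log10) per number

    def __post_init__(self) -> None:
        if min(self.Re, self.We, self.Bo) < 0:
            raise ValueError("dimensionless numbers must be non-negative")
        if not self.orders:
            self.orders = {k: order_of_magnitude(v)
                           for k, v in (("Re", self.Re), ("We", self.We),
                                        ("Bo", self.Bo))}


def order_of_magnitude(value: float) -> int | None:
    """floor(log10 value); None for zero."""
    return None if value == 0 else int(math.floor(math.log10(value)))


def characteristic_velocity(L_c_m: float, tau_c_s: float) -> float:
    """U = L/τ: distance the fluid front covers over the emergence time."""
    if tau_c_s <= 0:
        raise ValueError("characteristic time must be positive")
    if L_c_m < 0:
        raise ValueError("characteristic length must be non-negative")
    return L_c_m / tau_c_s


def dimensionless_numbers(scales: FluidScales, *, U: float | None = None
                          ) -> DimensionlessNumbers:
    """Re, We, Bo from the characteristic scales.

    If ``U`` is not supplied it is taken from ``scales.U``.
    """
    U = scales.U if U is None else U
    if U < 0:
        raise ValueError("velocity must be non-negative")
    rho, L, mu, sig, g = (scales.rho, scales.L_c, scales.mu,
                          scales.sigma_surface, scales.g)
    return DimensionlessNumbers(
        Re=rho * U * L / mu,
        We=rho * U**2 * L / sig,
        Bo=rho * g * L**2 / sig,
    )


def viscosity_from_capillary(times_s, positions_m, tube_radius_m: float,
                             sigma_surface: float = WATER_SURFACE_TENSION,
                             contact_angle_rad: float = 0.0,
                             monotone_tol: float = 0.05):
    """Viscosity from Lucas–Washburn imbibition into the pipette.

    Fits l² = slope·t through the origin; μ = σ·r·cosθ_c/(2·slope).
    Full wetting of glass (cosθ_c = 1) is the default.  Returns (mu, R²).

    The meniscus series must be (approximately) increasing — retraction is
    outside the Washburn model.
    """
    t = np.asarray(times_s, dtype=float)
    l = np.asarray(positions_m, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 meniscus samples")
    if tube_radius_m <= 0 or sigma_surface <= 0:
        raise ValueError("tube radius and surface tension must be positive")
    if math.cos(contact_angle_rad) <= 0:
        raise ValueError("contact angle must be below 90° for imbibition")
    dl = np.diff(l)
    span = float(l.max() - l.min())
    if span <= 0 or np.any(dl < -monotone_tol * span):
        raise ValueError("meniscus positions are not increasing beyond noise "
                         "tolerance; not a capillary-imbibition series")
    l2 = l * l
    stt = float(np.sum(t * t))
    if stt == 0:
        raise ValueError("all times are zero")
    slope = float(np.sum(t * l2) / stt)
    if slope <= 0:
        raise ValueError("non-positive l² vs t slope; cannot estimate viscosity")
    resid = l2 - slope * t
    ss_tot = float(np.sum((l2 - l2.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    mu = sigma_surface * tube_radius_m * math.cos(contact_angle_rad) / (2.0 * slope)
    return mu, r2
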