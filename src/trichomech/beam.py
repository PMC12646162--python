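"""Truncated-cone cantilever mechanics of the trichome stalk.

The trichome stalk is modeled as a homogeneous, linearly elastic
Euler–Bernoulli cantilever of length L tapering from base radius R2 to tip
radius R1 (R1 ≤ R2), with effective moment of area I = πR1³R2/4.  A
perpendicular tip load F⊥ then gives the tip deflection

    Δx = 4 F⊥ L³ / (3 π E R1³ R2),

i.e. a tip stiffness k_beam = 3πE·R1³R2/(4L³).  Two inversions are used:

* controlled pipette deflections of a stalk with known applied force yield
  the bending modulus E (observed range ~8–235 MPa for type VI stalks);
* observed stalk deflections during an insect contact, together with a
  measured E, yield the in-plane force component F⊥ and, through the contact
  angle, the full insect-applied force F_ins.

Units: μm, μN, MPa throughout (MPa·μm² = μN, so no conversion factors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrichomeGeometry",
    "BendingModulus",
    "InsectForceEstimate",
    "cone_stiffness",
    "bending_modulus_from_deflection",
    "bending_modulus_ensemble",
    "insect_force",
    "propagate_uncertainty",
]

#: default relative uncertainty on the stalk length L when none is given
#: (stalk bases are often out of frame, so L is the least certain geometry input)
DEFAULT_SIGMA_L_REL = 0.20

#: smallest |cos θ| for which the axial-angle division is attempted
COS_THETA_TOL = 1e-6


@dataclass
class TrichomeGeometry:
    """Stalk geometry: length L to the intermediate cell, radii R1 (top) ≤ R2 (base), μm."""

    L: float
    R1: float
    R2: float

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("stalk length L must be positive")
        if not 0 < self.R1 <= self.R2:
            raise ValueError("radii must satisfy 0 < R1 <= R2")


@dataclass
class BendingModulus:
    """Bending modulus of the stalk material, MPa, with spread over stalks."""

    E: float
    sigma_E: float = 0.0
    n: int = 1

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("bending modulus must be positive")
        if self.sigma_E < 0:
            raise ValueError("sigma_E must be non-negative")


@dataclass
class InsectForceEstimate:
    """Insect-applied force recovered from a stalk deflection."""

    F_perp: float        # in-plane (perpendicular-to-stalk) component, μN
    theta_axis: float    # rad, angle between applied force and imaging plane
    F_ins: float         # full applied force, μN
    sigma_F: float       # first-order propagated uncertainty, μN
    convention: str      # "divide" (default) or "literal"

    @property
    def interval(self) -> tuple[float, float]:
        """±1σ interval, lower edge clipped at zero (forces are positive)."""
        return (max(0.0, self.F_ins - self.sigma_F), self.F_ins + self.sigma_F)


def cone_stiffness(geom: TrichomeGeometry, E_MPa: float) -> float:
    """Tip stiffness (μN μm⁻¹) of the truncated-cone cantilever.

    k_beam = 3πE·R1³R2/(4L³).  For R1 = R2 = R this reduces to the uniform
    cylinder result 3E(πR⁴/4)/L³.
    """
    if E_MPa <= 0:
        raise ValueError("bending modulus must be positive")
    return 3.0 * math.pi * E_MPa * geom.R1**3 * geom.R2 / (4.0 * geom.L**3)


def bending_modulus_from_deflection(F_perp_uN: float, dx_um: float,
                                    geom: TrichomeGeometry) -> float:
    """Bending modulus (MPa) from one controlled deflection.

    E = 4·F⊥·L³/(3π·R1³·R2·Δx) — the algebraic inverse of the cone
    stiffness relation.
    """
    if dx_um <= 0:
        raise ValueError("deflection must be positive")
    if F_perp_uN <= 0:
        raise ValueError("applied force must be positive")
    return 4.0 * F_perp_uN * geom.L**3 / (3.0 * math.pi * geom.R1**3 * geom.R2 * dx_um)


def bending_modulus_ensemble(forces_uN, deflections_um, geoms) -> BendingModulus:
    """Mean ± SD bending modulus over repeated stalk measurements."""
    forces = np.atleast_1d(np.asarray(forces_uN, dtype=float))
    dxs = np.atleast_1d(np.asarray(deflections_um, dtype=float))
    if isinstance(geoms, TrichomeGeometry):
        geoms = [geoms] * len(forces)
    Es = np.array([bending_modulus_from_deflection(F, dx, g)
                   for F, dx, g in zip(forces, dxs, geoms, strict=True)])
    sd = float(Es.std(ddof=1)) if len(Es) > 1 else 0.0
    return BendingModulus(E=float(Es.mean()), sigma_E=sd, n=len(Es))


def propagate_uncertainty(partials, sigmas) -> float:
    """First-order (delta-method) uncertainty: sqrt(Σ (∂f/∂xᵢ · σᵢ)²)."""
    partials = np.asarray(partials, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    if np.any(sigmas < 0):
        raise ValueError("sigmas must be non-negative")
    return float(np.sqrt(np.sum((partials * sigmas) ** 2)))


def insect_force(dx_um: float, geom: TrichomeGeometry, modulus: BendingModulus,
                 theta_axis_rad: float = 0.0, *, sigma_L_um: float | None = None,
                 sigma_dx_um: float = 0.0,
                 convention: str = "divide") -> InsectForceEstimate:
    """Insect-applied force from an observed stalk deflection.

    F⊥ = k_beam(geom, E)·Δx is the force component in the imaging plane,
    perpendicular to the stalk axis.  θ is the angle between the applied
    force direction and that in-plane perpendicular; under the default
    ``"divide"`` convention the full force is F_ins = F⊥/cosθ, so the
    resultant is never shorter than its measured component.  The
    ``"literal"`` convention F_ins = F⊥·cosθ is retained for comparison.

    Uncertainty combines σ_E, σ_L (default 20% of L — stalk bases are often
    not visible, making L the dominant error source: F⊥ ∝ L⁻³) and
    optionally σ_Δx, by the first-order delta method.
    """
    if dx_um < 0:
        raise ValueError("deflection must be non-negative")
    if convention not in ("divide", "literal"):
        raise ValueError("convention must be 'divide' or 'literal'")
    c = math.cos(theta_axis_rad)
    if convention == "divide" and abs(c) < COS_THETA_TOL:
        raise ValueError("force nearly axial: unrecoverable (cos θ ≈ 0 means "
                         "the in-plane component carries no information)")
    if sigma_L_um is None:
        sigma_L_um = DEFAULT_SIGMA_L_REL * geom.L

    k_beam = cone_stiffness(geom, modulus.E)
    F_perp = k_beam * dx_um
    angle_factor = (1.0 / c) if convention == "divide" else c
    F_ins = F_perp * angle_factor

    # ∂F/∂E = F/E, ∂F/∂L = −3F/L, ∂F/∂Δx = F/Δx (F ∝ E·L⁻³·Δx)
    dF_dE = F_ins / modulus.E
    dF_dL = -3.0 * F_ins / geom.L
    partials = [dF_dE, dF_dL]
    sigmas = [modulus.sigma_E, sigma_L_um]
    if sigma_dx_um > 0:
        if dx_um == 0:
            raise ValueError("cannot propagate a deflection uncertainty at zero deflection")
        partials.append(F_ins / dx_um)
        sigmas.append(sigma_dx_um)
    sigma_F = propagate_uncertainty(partials, sigmas)
    return InsectForceEstimate(F_perp=F_perp, theta_axis=theta_axis_rad,
                               F_ins=F_ins, sigma_F=sigma_F,
                               convention=convention)
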