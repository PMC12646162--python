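"""Force-loading curves from calibrated pipette trajectories.

During a rupture experiment the pipette tip translates at constant speed,
contacts the trichome gland head, loads it elastically (the tip slows and the
pipette bends), and at rupture snaps back to its free trajectory.  The
position trace therefore shows two constant-slope regimes before rupture; the
applied force is F(t) = k·Δx(t) where Δx is the gap between the extrapolated
free trajectory and the observed position.

This module segments the trace into the two regimes (exhaustive two-segment
least squares), converts displacement to force, detects the rupture as the
force maximum followed by a steep drop, rescales curves by their rupture
point for ensemble collapse, and converts rupture forces into junction
torques and critical bending stresses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calibration import PipetteCalibration
from .trajectory import TrackedTrajectory

__all__ = [
    "ForceCurve",
    "RuptureEvent",
    "SegmentationResult",
    "NoContactError",
    "NoRuptureError",
    "segment_trajectory",
    "force_series",
    "detect_rupture",
    "rescale_curve",
    "collapse_ensemble",
    "second_moment_area",
    "torque_and_stress",
    "analyze_trajectory",
]


class NoContactError(RuntimeError):
    """The trajectory shows no slope reduction compatible with contact."""


class NoRuptureError(RuntimeError):
    """The force curve contains no qualifying drop."""


@dataclass
class SegmentationResult:
    """Two-regime split of a position trace.

    Slopes/intercepts describe the scalar position (projection of (x, y)
    onto the free-motion direction) as linear functions of absolute time.
    """

    t_contact: float           # absolute time of contact onset, s
    idx_contact: int           # index of the breakpoint sample
    free_slope: float          # μm/s
    free_intercept: float      # μm
    contact_slope: float       # μm/s
    contact_intercept: float   # μm
    sse: float                 # total squared error of the two fits
    times: np.ndarray = field(repr=False)          # absolute times used
    scalar_pos: np.ndarray = field(repr=False)     # projected positions, μm
    direction: np.ndarray = field(repr=False)      # unit vector in (x, y)


@dataclass
class ForceCurve:
    """F(t) during contact, time origin at contact onset."""

    times: np.ndarray          # s, relative to contact onset, times[0] == 0
    force: np.ndarray          # μN
    t_contact: float           # absolute contact time, s
    k_used: float              # μN μm⁻¹
    free_slope: float          # μm s⁻¹
    t_r: float | None = None   # rupture time relative to contact, s
    F_r: float | None = None   # rupture force, μN
    i_r: int | None = None     # index of the rupture sample
    post_slope: float | None = None  # μm s⁻¹, refit after rupture

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class RuptureEvent:
    """One rupture with its lever geometry, torque and critical stress.

    Also used as generator ground truth, in which case only the timing and
    force fields are populated.
    """

    F_r: float                         # μN
    t_contact: float | None = None     # absolute, s
    t_r: float | None = None           # relative to contact, s
    lever_arm: float | None = None     # r, μm
    theta_torque: float | None = None  # rad, angle between force and lever
    junction_radius: float | None = None  # R, μm
    torque: float | None = None        # μN·μm
    critical_stress: float | None = None  # MPa
    species: str | None = None
    location: str | None = None
    curve: ForceCurve | None = None


def _scalar_position(traj: TrackedTrajectory):
    """Project (x, y) onto the direction of net motion.

    Deflection is measured along the pipette's translation axis; projecting
    makes the analysis invariant to the camera's in-plane orientation.
    """
    v = traj.valid()
    dx = v.x[-1] - v.x[0]
    dy = v.y[-1] - v.y[0]
    norm = math.hypot(dx, dy)
    if norm == 0:
        raise ValueError("trajectory shows no net motion; cannot define a "
                         "translation axis")
    u = np.array([dx / norm, dy / norm])
    s = v.x * u[0] + v.y * u[1]
    return v.times, s, u


def _two_segment_sse(t: np.ndarray, s: np.ndarray, min_seg: int):
    """SSE of independent line fits on [0, b) and [b, n) for every split b.

    Closed form from prefix sums; O(n) overall.  Returns (splits, sse_left,
    sse_right, slopes_left, slopes_right, intercepts_left, intercepts_right).
    """
    n = len(t)
    cums = {name: np.cumsum(arr) for name, arr in
            (("n", np.ones(n)), ("t", t), ("s", s),
             ("tt", t * t), ("ss", s * s), ("ts", t * s))}

    def seg_stats(sums):
        m, St, Ss, Stt, Sss, Sts = (sums[k] for k in ("n", "t", "s", "tt", "ss", "ts"))
        vart = Stt - St * St / m
        cov = Sts - St * Ss / m
        vars_ = Sss - Ss * Ss / m
        slope = np.where(vart > 0, cov / np.where(vart > 0, vart, 1.0), 0.0)
        intercept = (Ss - slope * St) / m
        sse = vars_ - slope * cov
        return np.maximum(sse, 0.0), slope, intercept

    splits = np.arange(min_seg, n - min_seg + 1)
    left = {k: c[splits - 1] for k, c in cums.items()}
    right = {k: c[n - 1] - c[splits - 1] for k, c in cums.items()}
    sse_l, slope_l, int_l = seg_stats(left)
    sse_r, slope_r, int_r = seg_stats(right)
    return splits, sse_l, sse_r, slope_l, slope_r, int_l, int_r


def _rupture_jump_index(s: np.ndarray, window: int = 8,
                        n_sigmas: float = 5.0) -> int | None:
    """Index of the last pre-rupture sample, or None if no clear snap-back.

    Compares the mean position over the ``window`` samples after each index
    with the mean over the ``window`` before it.  The release of the stored
    deflection adds an extra forward jump on top of the ordinary per-frame
    advance; the candidate is accepted only if it exceeds the trace's median
    windowed advance by ``n_sigmas`` robust standard deviations.
    """
    n = len(s)
    if n < 3 * window:
        return None
    cs = np.concatenate([[0.0], np.cumsum(s)])
    i = np.arange(window, n - window)
    before = (cs[i + 1] - cs[i + 1 - window]) / window   # mean s[i-w+1 .. i]
    after = (cs[i + 1 + window] - cs[i + 1]) / window    # mean s[i+1 .. i+w]
    d = after - before
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    if d.max() <= med + n_sigmas * 1.4826 * mad:
        return None
    j0 = int(i[np.argmax(d)])
    # refine to the snap-back step itself: the single largest frame-to-frame
    # advance in the neighbourhood (the windowed estimate can land a few
    # samples off, which would leak post-rupture samples into the fit window)
    lo = max(0, j0 - window)
    hi = min(n - 1, j0 + window)
    return lo + int(np.argmax(np.diff(s[lo: hi + 1])))


def segment_trajectory(traj: TrackedTrajectory, *, min_seg: int = 5,
                       slope_reduction_margin: float = 0.1,
                       truncate_at_rupture: bool = True,
                       ) -> SegmentationResult:
    """Locate contact onset by exhaustive two-segment least squares.

    Every candidate breakpoint is scored by the total squared error of
    independent line fits to the samples before and after it; the minimiser
    wins (earliest index on exact ties).  A breakpoint only qualifies if the
    second slope is smaller in magnitude than the first by at least
    ``slope_reduction_margin`` (relative), otherwise ``NoContactError``.

    With ``truncate_at_rupture`` (default) the search is restricted to the
    samples before the rupture snap-back — the single large forward jump the
    tip makes when the stored deflection releases — so the searched window
    contains only the free and contact regimes.  The jump is located by
    windowed mean-differencing and accepted only when it stands out robustly
    from the trace's ordinary frame-to-frame advance, so two-regime traces
    without a rupture are left untouched.  The post-rupture regime is
    analysed separately by :func:`detect_rupture`.
    """
    t, s, u = _scalar_position(traj)
    n = len(t)
    if n < 2 * min_seg:
        raise ValueError(f"trajectory too short to segment ({n} samples, "
                         f"need ≥ {2 * min_seg})")

    if truncate_at_rupture:
        i_jump = _rupture_jump_index(s)
        if i_jump is not None and i_jump + 1 >= 2 * min_seg:
            t, s = t[: i_jump + 1], s[: i_jump + 1]
            n = len(t)

    splits, sse_l, sse_r, slope_l, slope_r, int_l, int_r = _two_segment_sse(
        t, s, min_seg)
    total = sse_l + sse_r
    with np.errstate(divide="ignore", invalid="ignore"):
        reduction = (np.abs(slope_l) - np.abs(slope_r)) / np.where(
            slope_l != 0, np.abs(slope_l), 1.0)
    valid = reduction >= slope_reduction_margin
    if not np.any(valid):
        raise NoContactError(
            "no breakpoint reduces the slope by the required margin "
            f"({slope_reduction_margin:.0%}); no contact detected")
    total = np.where(valid, total, np.inf)
    # Earliest breakpoint among numerical ties: on noise-free data both the
    # kink sample and its successor give (exactly) zero error, and rounding
    # may order them arbitrarily; the kink sample is the physical onset.
    best = float(np.min(total))
    tol = 1e-10 * float(np.sum(s * s)) / len(s) + 1e-300
    j = int(np.argmax(total <= best + tol))
    b = int(splits[j])
    return SegmentationResult(
        t_contact=float(t[b]), idx_contact=b,
        free_slope=float(slope_l[j]), free_intercept=float(int_l[j]),
        contact_slope=float(slope_r[j]), contact_intercept=float(int_r[j]),
        sse=float(total[j]), times=t, scalar_pos=s, direction=u,
    )


def force_series(traj: TrackedTrajectory, seg: SegmentationResult,
                 calibration: PipetteCalibration | float) -> ForceCurve:
    """Convert the contact-regime position deficit into force.

    Δx(t) = (extrapolated free position) − (observed position) for
    t ≥ t_contact; F(t) = k·Δx(t).
    """
    k = calibration.k if isinstance(calibration, PipetteCalibration) else float(calibration)
    if k <= 0:
        raise ValueError("spring constant must be positive")
    t, s, _ = _scalar_position(traj)
    mask = t >= seg.t_contact
    t_c = t[mask]
    dx = (seg.free_intercept + seg.free_slope * t_c) - s[mask]
    return ForceCurve(
        times=t_c - seg.t_contact, force=k * dx,
        t_contact=seg.t_contact, k_used=k, free_slope=seg.free_slope,
    )


def detect_rupture(curve: ForceCurve, *, drop_frac: float = 0.5,
                   drop_window: int = 5) -> ForceCurve:
    """Find the rupture: the force maximum followed by a steep drop.

    Rupture is declared at the global maximum F_r of the curve provided the
    force falls by at least ``drop_frac``·F_r within ``drop_window`` samples
    afterwards (a residual sticking force after the drop is tolerated).
    Returns the curve with t_r, F_r and the post-rupture slope filled in.
    """
    F = curve.force
    if len(F) < 2:
        raise NoRuptureError("force curve too short")
    i_r = int(np.argmax(F))
    F_r = float(F[i_r])
    if F_r <= 0:
        raise NoRuptureError("force never becomes positive; no rupture detected")
    tail = F[i_r + 1: i_r + 1 + drop_window]
    if len(tail) == 0 or float(np.min(tail)) > (1.0 - drop_frac) * F_r:
        raise NoRuptureError(
            f"no drop of ≥ {drop_frac:.0%} of the peak force within "
            f"{drop_window} samples after the maximum; no rupture detected")
    t_r = float(curve.times[i_r])
    if t_r <= 0:
        raise NoRuptureError("force maximum at contact onset; no loading phase")

    # post-rupture slope of the position proxy: ds/dt = free_slope - (dF/dt)/k
    post_t = curve.times[i_r + 1:]
    post_F = F[i_r + 1:]
    post_slope = None
    if len(post_t) >= 2:
        dFdt = float(np.polyfit(post_t, post_F, 1)[0])
        post_slope = curve.free_slope - dFdt / curve.k_used
    curve.t_r, curve.F_r, curve.i_r, curve.post_slope = t_r, F_r, i_r, post_slope
    return curve


def rescale_curve(curve: ForceCurve):
    """Normalize to (t/t_r, F/F_r) on the loading branch.

    The returned curve ends exactly at (1, 1) — the rupture point — so an
    ensemble of rescaled curves can be superposed to test for a shared
    fracture mechanism.
    """
    if curve.t_r is None or curve.F_r is None:
        raise ValueError("curve has no detected rupture; run detect_rupture first")
    if curve.t_r <= 0 or curve.F_r <= 0:
        raise ValueError("rupture time and force must be positive to rescale")
    sl = slice(0, curve.i_r + 1)
    return curve.times[sl] / curve.t_r, curve.force[sl] / curve.F_r


def collapse_ensemble(curves, n_grid: int = 101):
    """Pointwise mean ± SD of rescaled curves on a common grid in [0, 1].

    Each curve is rescaled by its own rupture point and linearly interpolated
    onto the shared grid.  Returns (grid, mean, sd).
    """
    curves = list(curves)
    if len(curves) < 2:
        raise ValueError("need at least 2 curves for an ensemble")
    grid = np.linspace(0.0, 1.0, n_grid)
    stack = np.empty((len(curves), n_grid))
    for i, c in enumerate(curves):
        ts, fs = rescale_curve(c)
        stack[i] = np.interp(grid, ts, fs)
    return grid, stack.mean(axis=0), stack.std(axis=0)


def second_moment_area(R_um: float) -> float:
    """Axial second moment of area of a solid circular section: I_z = πR⁴/4 (μm⁴)."""
    if R_um <= 0:
        raise ValueError("junction radius must be positive")
    return math.pi * R_um**4 / 4.0


def torque_and_stress(curve_or_Fr, lever_arm_um: float, theta_rad: float,
                      junction_radius_um: float, *, species: str | None = None,
                      location: str | None = None) -> RuptureEvent:
    """Rupture torque and critical junction stress from the lever geometry.

    τ_r = r·F_r·sinθ with θ the angle between the applied force and the
    lever vector from the junction axis; the bending stress is maximal at
    the junction boundary, σ_c = R·τ_r/I_z = 4τ_r/(πR³).  With forces in μN
    and lengths in μm, σ_c comes out directly in MPa (μN μm⁻² ≡ MPa).
    """
    if isinstance(curve_or_Fr, ForceCurve):
        curve = curve_or_Fr
        if curve.F_r is None:
            raise ValueError("curve has no detected rupture")
        F_r = curve.F_r
    else:
        curve, F_r = None, float(curve_or_Fr)
    if lever_arm_um <= 0:
        raise ValueError("lever arm must be positive")
    if not 0.0 <= theta_rad <= math.pi:
        raise ValueError("theta must lie in [0, π]")
    R = junction_radius_um
    tau_r = lever_arm_um * F_r * math.sin(theta_rad)
    sigma_c = R * tau_r / second_moment_area(R)  # == 4 τ_r / (π R³)
    return RuptureEvent(
        F_r=F_r, t_contact=curve.t_contact if curve else None,
        t_r=curve.t_r if curve else None,
        lever_arm=lever_arm_um, theta_torque=theta_rad, junction_radius=R,
        torque=tau_r, critical_stress=sigma_c,
        species=species, location=location, curve=curve,
    )


def analyze_trajectory(traj: TrackedTrajectory,
                       calibration: PipetteCalibration | float,
                       **segment_kwargs) -> ForceCurve:
    """Segment, convert to force and detect the rupture in one call."""
    seg = segment_trajectory(traj, **segment_kwargs)
    curve = force_series(traj, seg, calibration)
    return detect_rupture(curve)
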