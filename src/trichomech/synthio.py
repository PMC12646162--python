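"""Synthetic inputs with known ground truth for every pipeline stage.

Real inputs to this pipeline are microscopy videos and position traces of
micropipette rupture experiments.  The generators here emulate their
statistical structure — two-slope trajectories at the standard 33 μm s⁻¹
translation speed, spring constants in the manufactured range
0.04–1.17 μN μm⁻¹, rupture forces spanning 1–24 μN, the four
species × location groups at their observed means/SDs/counts, and
truncated-cone deflection series over the observed bending-modulus range
8–235 MPa — while recording exact ground truth, so that every inference
stage can be validated as a round trip.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beam import TrichomeGeometry, cone_stiffness
from .calibration import droplet_weight
from .forcecurve import RuptureEvent
from .stats import iqr_outliers
from .trajectory import TrackedTrajectory

__all__ = [
    "RuptureScenario",
    "GroupSpec",
    "DEFAULT_GROUPS",
    "gen_rupture_trajectory",
    "gen_calibration_droplets",
    "gen_two_pipette_series",
    "gen_trichome_deflection",
    "gen_group_dataset",
    "gen_blob_image_stack",
    "gen_capillary_flow",
]

#: pipette translation speed used in all experiments, μm s⁻¹
DEFAULT_FREE_SPEED = 33.0
#: manufactured spring-constant range, μN μm⁻¹
K_RANGE = (0.04, 1.17)
#: observed rupture-force range, μN
F_R_RANGE = (1.0, 24.0)
#: tracking noise default, μm (sub-pixel at the cameras' magnification;
#: at k ≈ 0.1 μN μm⁻¹ this carries ~10 nN of force noise, matching the
#: tens-to-hundreds of nanonewtons quoted for the measurement uncertainty)
DEFAULT_NOISE_SD = 0.1


@dataclass
class RuptureScenario:
    """Parameters of one simulated rupture experiment.

    ``k_true`` and ``F_r_true`` default to None, meaning they are drawn
    uniformly from the manufactured/observed ranges using ``seed``.
    ``loading_rate`` (μN s⁻¹) defaults to 0.5·k·v_free — the tip slows to
    half its free speed during loading, matching the roughly halved contact
    slope seen in measured traces.  The loading rate is physically bounded
    by k·v_free (a pipette translated at v_free cannot load faster), so
    stiff pipettes rupturing weak heads load in a fraction of a second and
    contribute only a few loading samples at the default frame rate — as in
    the real recordings, where such events are nearly instantaneous.
    """

    k_true: float | None = None          # μN μm⁻¹
    v_free: float = DEFAULT_FREE_SPEED   # μm s⁻¹
    F_r_true: float | None = None        # μN
    t_contact: float = 2.0               # s
    loading_rate: float | None = None    # μN s⁻¹
    noise_sd: float = DEFAULT_NOISE_SD   # μm
    frame_rate: float = 50.0             # Hz
    seed: int = 0
    post_duration: float = 1.0           # s of trace after rupture
    duration: float | None = None        # total trace length; None = auto
    residual_force: float = 0.0          # μN sticking force after rupture

    def __post_init__(self) -> None:
        # always consume two draws so the trace-noise stream that follows is
        # the same whether or not k/F_r were given explicitly
        rng = np.random.default_rng(self.seed)
        k_draw = float(rng.uniform(*K_RANGE))
        F_draw = float(rng.uniform(*F_R_RANGE))
        if self.k_true is None:
            self.k_true = k_draw
        if self.F_r_true is None:
            self.F_r_true = F_draw
        if self.loading_rate is None:
            self.loading_rate = 0.5 * self.k_true * self.v_free
        if self.k_true <= 0 or self.v_free <= 0 or self.F_r_true <= 0:
            raise ValueError("k_true, v_free and F_r_true must be positive")
        if self.loading_rate <= 0:
            raise ValueError("loading rate must be positive")
        if self.noise_sd < 0 or self.frame_rate <= 0 or self.t_contact < 0:
            raise ValueError("invalid noise_sd / frame_rate / t_contact")
        if self.residual_force < 0 or self.residual_force >= self.F_r_true:
            raise ValueError("residual force must be in [0, F_r_true)")


def gen_rupture_trajectory(scenario: RuptureScenario
                           ) -> tuple[TrackedTrajectory, RuptureEvent]:
    """Simulate the pipette-tip trace of one rupture experiment.

    Free motion at ``v_free`` until contact; during loading the deflection
    Δx(t) = F(t)/k grows linearly at ``loading_rate``/k (kinematically rigid
    loading — observed loading slopes are linear), so the apparent tip speed
    drops; at rupture the tip snaps back to the free line (minus any
    residual sticking force) and resumes the free slope.  Contact onset and
    rupture are snapped to the sampling grid and the ground truth records
    the *realized* rupture force/time, so noise-free traces invert exactly.

    Returns (trajectory, ground truth) where the ground truth is a
    :class:`RuptureEvent` with F_r, absolute t_contact and t_r relative to
    contact.
    """
    sc = scenario
    dt = 1.0 / sc.frame_rate
    t_contact = round(sc.t_contact / dt) * dt
    n_load = max(1, round(sc.F_r_true / sc.loading_rate / dt))
    t_load = n_load * dt
    F_r = sc.loading_rate * t_load
    t_r_abs = t_contact + t_load

    duration = sc.duration if sc.duration is not None else t_r_abs + sc.post_duration
    if t_r_abs + dt > duration + 1e-12:
        raise ValueError(
            f"rupture at t = {t_r_abs:.3f} s does not fit in the "
            f"{duration:.3f} s trace; lengthen the trace or raise the "
            "loading rate")

    times = np.arange(0.0, duration + dt / 2, dt)
    x = sc.v_free * times
    in_contact = (times > t_contact + dt / 2) & (times <= t_r_abs + dt / 2)
    x[in_contact] -= (sc.loading_rate / sc.k_true) * (times[in_contact] - t_contact)
    after = times > t_r_abs + dt / 2
    x[after] -= sc.residual_force / sc.k_true
    y = np.zeros_like(x)

    rng = np.random.default_rng(sc.seed)
    rng.uniform(size=2)  # skip the scenario-sampling draws
    if sc.noise_sd > 0:
        x = x + rng.normal(0.0, sc.noise_sd, size=len(x))
        y = y + rng.normal(0.0, sc.noise_sd, size=len(y))

    traj = TrackedTrajectory(times, x, y, frame_rate=sc.frame_rate,
                             source=f"synthio rupture seed={sc.seed}")
    truth = RuptureEvent(F_r=F_r, t_contact=t_contact, t_r=t_load)
    return traj, truth


def gen_calibration_droplets(k_true: float, n: int = 10,
                             noise_frac: float = 0.01, seed: int = 0,
                             radius_range_um: tuple[float, float] = (150.0, 350.0),
                             ) -> pd.DataFrame:
    """Droplet calibration series: (radius_um, deflection_um).

    deflection_i = weight(radius_i)/k_true · (1 + ε_i), ε ~ N(0, noise_frac²).
    """
    if k_true <= 0:
        raise ValueError("k_true must be positive")
    if n < 2:
        raise ValueError("need at least 2 droplets to fit a slope")
    rng = np.random.default_rng(seed)
    radii = np.linspace(*radius_range_um, n)
    weights = np.array([droplet_weight(r) for r in radii])
    eps = rng.normal(0.0, noise_frac, size=n) if noise_frac > 0 else np.zeros(n)
    deflections = weights / k_true * (1.0 + eps)
    return pd.DataFrame({"radius_um": radii, "deflection_um": deflections})


def gen_two_pipette_series(k_true: float, k_ref: float, n: int = 8,
                           noise_frac: float = 0.01, seed: int = 0,
                           d_ref_range_um: tuple[float, float] = (2.0, 20.0),
                           ) -> pd.DataFrame:
    """Two-pipette pressing series: (d_ref_um, d_unknown_um).

    Quasi-static force balance: k_ref·d_ref = k_true·d_unknown.
    """
    if k_true <= 0 or k_ref <= 0:
        raise ValueError("spring constants must be positive")
    if n < 2:
        raise ValueError("need at least 2 presses")
    rng = np.random.default_rng(seed)
    d_ref = np.linspace(*d_ref_range_um, n)
    eps = rng.normal(0.0, noise_frac, size=n) if noise_frac > 0 else np.zeros(n)
    d_unknown = k_ref * d_ref / k_true * (1.0 + eps)
    return pd.DataFrame({"d_ref_um": d_ref, "d_unknown_um": d_unknown})


def gen_trichome_deflection(geometry: TrichomeGeometry, E_true: float,
                            F_ins_true: float, theta_axis_rad: float = 0.0,
                            noise_sd_um: float = 0.0, seed: int = 0,
                            n: int = 5) -> tuple[np.ndarray, dict]:
    """Repeated stalk-deflection measurements under a fixed applied force.

    The in-plane component is F⊥ = F_ins·cosθ (θ between the applied-force
    direction and the in-plane perpendicular to the stalk), and the
    noise-free deflection is Δx = F⊥/k_beam from the truncated-cone
    stiffness.  Returns (deflections, ground truth dict).
    """
    if E_true <= 0 or F_ins_true <= 0:
        raise ValueError("E_true and F_ins_true must be positive")
    c = math.cos(theta_axis_rad)
    if abs(c) < 1e-6:
        raise ValueError("cos θ ≈ 0: the in-plane deflection carries no "
                         "information about the applied force")
    F_perp = F_ins_true * c
    dx_true = F_perp / cone_stiffness(geometry, E_true)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd_um, size=n) if noise_sd_um > 0 else np.zeros(n)
    deflections = dx_true + noise
    truth = {"dx_true": dx_true, "F_perp": F_perp, "E_true": E_true,
             "F_ins_true": F_ins_true, "theta_axis_rad": theta_axis_rad}
    return deflections, truth


@dataclass
class GroupSpec:
    """One species × location group of rupture forces."""

    species: str
    location: str
    mean_F: float   # μN
    sd_F: float     # μN
    n: int          # non-outlier count
    n_outliers: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.sd_F < 0 or self.n_outliers < 0:
            raise ValueError("invalid group spec")


#: the observed group structure: means ± SDs (μN) and counts after outlier
#: removal, plus the 5 extreme values the screening step has to catch
DEFAULT_GROUPS = [
    GroupSpec("cultivar", "leaf", 5.0, 2.0, 16, n_outliers=1),
    GroupSpec("cultivar", "stem", 9.0, 3.0, 24, n_outliers=2),
    GroupSpec("wild", "leaf", 6.0, 3.0, 29, n_outliers=1),
    GroupSpec("wild", "stem", 4.0, 2.0, 10, n_outliers=1),
]


def _truncated_normal(rng, mean, sd, size):
    """N(mean, sd²) truncated at 0 by rejection (forces are positive)."""
    out = rng.normal(mean, sd, size=size)
    for _ in range(1000):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise RuntimeError("truncated-normal rejection failed to converge")


def gen_group_dataset(specs: list[GroupSpec] | None = None, seed: int = 0,
                      ) -> pd.DataFrame:
    """Grouped rupture forces with exactly labelled planted outliers.

    Non-outlier values are drawn per group from N(mean, sd²) truncated at
    zero; any clean draw that the pooled 1.5·IQR rule itself would flag is
    redrawn, so the clean sample contains no accidental outliers and the
    ground-truth labels are unambiguous (the redraw touches well under 1% of
    the probability mass, leaving the group means/SDs essentially at their
    nominal values).  Planted outliers are then placed beyond the pooled
    fence with margin, and the construction is verified by running the
    screening rule on the combined sample, redrawing the rare clean value
    that drifts past the combined-sample fence.

    Returns a long-format DataFrame (species, location, value,
    planted_outlier) where ``value`` is the rupture force in μN.
    """
    if specs is None:
        specs = DEFAULT_GROUPS
    if not specs:
        raise ValueError("need at least one group spec")
    rng = np.random.default_rng(seed)

    frames = []
    for g in specs:
        vals = _truncated_normal(rng, g.mean_F, g.sd_F, g.n)
        frames.append(pd.DataFrame({
            "species": g.species, "location": g.location, "value": vals,
            "planted_outlier": False}))
    df = pd.concat(frames, ignore_index=True)

    def _redraw(idx):
        g = next(s for s in specs
                 if s.species == df.at[idx, "species"]
                 and s.location == df.at[idx, "location"])
        df.at[idx, "value"] = _truncated_normal(rng, g.mean_F, g.sd_F, 1)[0]

    # clean pool: redraw the rare value its own pooled 1.5·IQR rule flags
    for _ in range(200):
        bad = iqr_outliers(df["value"].to_numpy())
        if not bad.any():
            break
        for idx in df.index[bad]:
            _redraw(idx)
    else:
        raise RuntimeError("could not confine clean draws inside IQR fences")

    total_outliers = sum(g.n_outliers for g in specs)
    if total_outliers == 0:
        return df

    for attempt in range(50):
        q1, q3 = np.quantile(df["value"], [0.25, 0.75])
        iqr = q3 - q1
        base_hi = q3 + 1.5 * iqr
        margin_scale = 1.5 ** min(attempt, 10)
        rows = []
        for j, g in enumerate(s for s in specs for _ in range(s.n_outliers)):
            offset = (1.0 + 0.5 * j + 0.25 * rng.random()) * margin_scale
            rows.append({"species": g.species, "location": g.location,
                         "value": base_hi + offset * iqr,
                         "planted_outlier": True})
        full = pd.concat([df, pd.DataFrame(rows)], ignore_index=True)
        mask = iqr_outliers(full["value"].to_numpy())
        planted = full["planted_outlier"].to_numpy()
        if np.array_equal(mask, planted):
            return full
        if np.all(mask[planted]):
            # a clean value drifted past the combined-sample fence: redraw it
            for idx in np.nonzero(mask & ~planted)[0]:
                _redraw(int(idx))
        # else: a planted value fell inside the fence; widen the margin
    raise RuntimeError("planted outliers could not be separated from the "
                       "clean pool by the IQR rule")


def gen_blob_image_stack(trajectory: TrackedTrajectory, blob_sd_px: float = 2.0,
                         peak_intensity: float = 400.0, background: float = 20.0,
                         pixel_size_um: float = 1.0, seed: int = 0,
                         shape: tuple[int, int] = (64, 64)) -> np.ndarray:
    """Render a trajectory as a bright-field-like blob stack.

    Each frame holds a 2-D Gaussian blob of SD ``blob_sd_px`` centered at
    the trajectory position (μm → px via ``pixel_size_um``) plus
    Poisson-distributed background counts.  Raises if any blob center comes
    within 3σ of the frame edge, naming the offending frame.
    """
    ny, nx = shape
    cx = trajectory.x / pixel_size_um
    cy = trajectory.y / pixel_size_um
    margin = 3.0 * blob_sd_px
    for i, (u, v) in enumerate(zip(cx, cy)):
        if not (margin <= u <= nx - 1 - margin and margin <= v <= ny - 1 - margin):
            raise ValueError(f"blob leaves the frame at frame {i}: "
                             f"center ({u:.1f}, {v:.1f}) px within {margin:.1f} px "
                             f"of the {nx}x{ny} frame edge")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:ny, 0:nx]
    stack = np.empty((len(trajectory), ny, nx))
    for i in range(len(trajectory)):
        blob = peak_intensity * np.exp(
            -((xx - cx[i]) ** 2 + (yy - cy[i]) ** 2) / (2.0 * blob_sd_px**2))
        if background > 0:
            blob = blob + rng.poisson(background, size=(ny, nx))
        stack[i] = blob
    return stack


def gen_capillary_flow(mu_true: float, tube_radius_m: float = 1e-5,
                       sigma_surface: float = 0.072, n: int = 20,
                       t_max_s: float = 5.0, noise_frac: float = 0.0,
                       seed: int = 0) -> pd.DataFrame:
    """Lucas–Washburn meniscus series l(t) for a fluid of known viscosity."""
    if mu_true <= 0 or n < 3:
        raise ValueError("mu_true must be positive and n >= 3")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_max_s, n)
    slope = sigma_surface * tube_radius_m / (2.0 * mu_true)
    l = np.sqrt(slope * t)
    if noise_frac > 0:
        l = l * (1.0 + rng.normal(0.0, noise_frac, size=n))
        l[0] = 0.0
    return pd.DataFrame({"time_s": t, "l_m": l})
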