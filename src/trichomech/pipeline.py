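"""End-to-end orchestration of the measurement chain.

One config (YAML or dict) drives a reproducible run: pipette calibration →
trajectory analysis (segmentation, force conversion, rupture detection) →
ensemble collapse → group statistics → stalk-beam insect-force inversion →
fluid characterization.  When no measured inputs are supplied the run uses
the synthetic generators, whose ground truth then doubles as an end-to-end
self check.

Every output CSV/JSON carries provenance (config hash, package version) and
the run is deterministic under a fixed seed.  A failure in any stage aborts
with the stage name and the offending input.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import fit_droplet_calibration, calibrate_from_csv
from .forcecurve import analyze_trajectory, collapse_ensemble, rescale_curve, torque_and_stress
from .trajectory import read_trajectory_csv
from .beam import TrichomeGeometry, BendingModulus, insect_force
from .fluidics import FluidScales, dimensionless_numbers, viscosity_from_capillary
from .stats import analyze_groups
from . import synthio

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """Raised when a stage fails; message names the stage and input."""


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "trichomech_results"
    # calibration: either a CSV path or synthetic droplet-series parameters
    calibration_csv: str | None = None
    k_true: float = 0.25            # μN μm⁻¹, used only for synthetic runs
    calibration_n: int = 10
    calibration_noise_frac: float = 0.01
    # trajectories: list of CSV paths, or the number of synthetic scenarios
    trajectory_csvs: list = field(default_factory=list)
    n_scenarios: int = 20
    noise_sd: float = synthio.DEFAULT_NOISE_SD
    # segmentation / rupture detection
    slope_reduction_margin: float = 0.1
    drop_frac: float = 0.5
    drop_window: int = 5
    # per-event lever geometry defaults (μm, degrees)
    lever_arm_um: float = 30.0
    theta_torque_deg: float = 90.0
    junction_radius_um: float = 12.0
    # group statistics
    alpha: float = 0.02
    # beam inversion
    stalk_L_um: float = 100.0
    stalk_R1_um: float = 5.0
    stalk_R2_um: float = 10.0
    E_MPa: float = 55.0
    sigma_E_MPa: float = 64.0
    insect_dx_um: float = 3.7
    theta_axis_deg: float = 0.0
    angle_convention: str = "divide"
    # fluidics
    fluid_mu: float = 0.1
    fluid_U: float = 1e-2
    fluid_L: float = 1e-5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        fields = asdict(self)
        fields.pop("outdir")  # where results land does not affect results
        blob = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name, fn, *args, input_id: str = "", **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        where = f" (input: {input_id})" if input_id else ""
        raise PipelineError(f"stage '{name}' failed{where}: {exc}") from exc


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full chain; returns the results bundle and writes ``outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": config.hash(), "version": __version__,
                  "seed": config.seed}

    # -- calibration -------------------------------------------------------
    if config.calibration_csv:
        calib = _stage("calibrate", calibrate_from_csv, config.calibration_csv,
                       input_id=config.calibration_csv)
    else:
        series = synthio.gen_calibration_droplets(
            config.k_true, n=config.calibration_n,
            noise_frac=config.calibration_noise_frac, seed=config.seed)
        calib = _stage("calibrate", fit_droplet_calibration,
                       series["radius_um"], series["deflection_um"],
                       input_id="synthetic droplet series")
    calib.to_json(out / "calibration.json")

    # -- trajectories → rupture events ------------------------------------
    curves, rows = [], []
    if config.trajectory_csvs:
        sources = [(p, read_trajectory_csv(p), None) for p in config.trajectory_csvs]
    else:
        sources = []
        for i in range(config.n_scenarios):
            # the simulated ruptures are performed with the same pipette the
            # calibration stage characterized
            sc = synthio.RuptureScenario(seed=(config.seed * 100003 + i) % 2**31,
                                         k_true=config.k_true,
                                         noise_sd=config.noise_sd)
            traj, truth = synthio.gen_rupture_trajectory(sc)
            sources.append((f"synthetic[{i}]", traj, truth))

    theta = math.radians(config.theta_torque_deg)
    for name, traj, truth in sources:
        curve = _stage("analyze-rupture", analyze_trajectory, traj, calib,
                       slope_reduction_margin=config.slope_reduction_margin,
                       input_id=str(name))
        curves.append(curve)
        event = torque_and_stress(curve, config.lever_arm_um, theta,
                                  config.junction_radius_um)
        row = {"source": name, "F_r_uN": curve.F_r, "t_r_s": curve.t_r,
               "t_contact_s": curve.t_contact, "free_slope_um_s": curve.free_slope,
               "post_slope_um_s": curve.post_slope,
               "torque_uN_um": event.torque, "critical_stress_MPa": event.critical_stress}
        if truth is not None:
            row["F_r_true_uN"] = truth.F_r
            row["t_r_true_s"] = truth.t_r
        rows.append(row)
    events = pd.DataFrame(rows)
    events.to_csv(out / "events.csv", index=False)

    if len(curves) >= 2:
        grid, mean, sd = collapse_ensemble(curves)
        pd.DataFrame({"t_over_tr": grid, "mean_F_over_Fr": mean,
                      "sd_F_over_Fr": sd}).to_csv(out / "collapse.csv", index=False)

    # -- group statistics ---------------------------------------------------
    groups = synthio.gen_group_dataset(seed=config.seed)
    stats_res = _stage("group-stats", analyze_groups,
                       groups[["species", "location", "value"]],
                       alpha=config.alpha, input_id="synthetic group dataset")
    stats_res["summary"].to_csv(out / "group_summary.csv", index=False)
    stats_res["anova"].to_csv(out / "anova.csv")
    stats_res["tukey"].to_csv(out / "tukey.csv", index=False)

    # -- beam inversion -----------------------------------------------------
    geom = TrichomeGeometry(L=config.stalk_L_um, R1=config.stalk_R1_um,
                            R2=config.stalk_R2_um)
    modulus = BendingModulus(E=config.E_MPa, sigma_E=config.sigma_E_MPa)
    est = _stage("insect-force", insect_force, config.insect_dx_um, geom, modulus,
                 math.radians(config.theta_axis_deg),
                 convention=config.angle_convention, input_id="config beam event")

    # -- fluidics -----------------------------------------------------------
    scales = FluidScales(mu=config.fluid_mu, U=config.fluid_U, L_c=config.fluid_L)
    nums = dimensionless_numbers(scales)
    washburn = synthio.gen_capillary_flow(config.fluid_mu, seed=config.seed)
    mu_fit, r2 = _stage("fluidics", viscosity_from_capillary,
                        washburn["time_s"], washburn["l_m"], 1e-5,
                        input_id="synthetic capillary series")

    report = {
        "provenance": provenance,
        "calibration": {"k": calib.k, "sigma_k": calib.sigma_k,
                        "method": calib.method},
        "n_events": len(events),
        "mean_F_r_uN": float(events["F_r_uN"].mean()) if len(events) else None,
        "group_letters": stats_res["letters"],
        "n_outliers_removed": stats_res["n_outliers"],
        "insect_force": {"F_perp_uN": est.F_perp, "F_ins_uN": est.F_ins,
                         "sigma_F_uN": est.sigma_F,
                         "interval_uN": list(est.interval)},
        "fluidics": {"Re": nums.Re, "We": nums.We, "Bo": nums.Bo,
                     "orders": nums.orders, "mu_fit_Pa_s": mu_fit,
                     "washburn_r2": r2},
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
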