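"""Pipeline configuration and stage orchestration.

A RunConfig (usually loaded from YAML) names the input artifacts and the
stages to run; run_pipeline executes them in the fixed order
structure -> dynamics -> thermal -> model and writes a machine-readable
JSON summary in which every numeric output carries a units field.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import diffusion_coefficient, msd
from .model import (
    InterfaceStack,
    fit_steady_parameters,
    fit_transient,
    predict_critical_power,
    steady_state_profile,
    transient_graphene_temperature,
)
from .structure import density_profile, first_peak_mass, water_layer_thickness
from .thermal import (
    DeltaTCurve,
    GrapheneSheet,
    TemperatureProfile,
    TemperatureSeries,
    critical_power,
    kapitza_conductance,
    relaxation_time,
)
from .trajectory import read_trajectory

log = logging.getLogger("nanoheat")

STAGE_ORDER = ("structure", "dynamics", "thermal", "model")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    stages: list
    output_dir: str = "nanoheat_out"
    seed: int = 0
    structure: dict = field(default_factory=dict)
    dynamics: dict = field(default_factory=dict)
    thermal: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {"stages", "output_dir", "seed", "structure", "dynamics", "thermal", "model"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self):
        if not self.stages:
            raise ValueError("config selects no stages")
        for s in self.stages:
            if s not in STAGE_ORDER:
                raise ValueError(f"unknown stage {s!r}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        for key in ("structure", "dynamics"):
            if key in self.stages:
                section = getattr(self, key)
                traj = section.get("trajectory")
                if not traj:
                    raise ValueError(f"stage {key!r} needs a 'trajectory' path")
                if not Path(traj).exists():
                    raise ValueError(f"stage {key!r}: trajectory {traj!r} does not exist")
        if "thermal" in self.stages:
            if not (self.thermal.get("series") or self.thermal.get("curve")):
                raise ValueError("thermal stage needs 'series' and/or 'curve' input")
            for k in ("series", "curve"):
                if self.thermal.get(k) and not Path(self.thermal[k]).exists():
                    raise ValueError(f"thermal input {self.thermal[k]!r} does not exist")
        if "model" in self.stages:
            if "stack" not in self.model:
                raise ValueError("model stage needs a 'stack' parameter block")
            for k in ("profile_csv", "series_csv"):
                if self.model.get(k) and not Path(self.model[k]).exists():
                    raise ValueError(f"model input {self.model[k]!r} does not exist")
            if self.model.get("fit") and not (
                self.model.get("profile_csv") or self.model.get("series_csv")
            ):
                raise ValueError(
                    "model fit requested but no temperature data "
                    "(profile_csv or series_csv) provided"
                )
        for section in (self.structure, self.dynamics, self.thermal, self.model):
            for k, v in section.items():
                if k in ("bin_width", "power", "delta", "z_s", "delta_T_c") and (
                    not isinstance(v, (int, float)) or v <= 0
                ):
                    raise ValueError(f"option {k}={v!r} must be a positive number")


def _q(value, units):
    if isinstance(value, (np.floating, np.integer)):
        value = value.item()
    return {"value": value, "units": units}


def _run_structure(cfg: RunConfig, outdir: Path) -> dict:
    opts = cfg.structure
    traj = read_trajectory(opts["trajectory"], opts.get("dialect", "extended_xyz"))
    profile = density_profile(
        traj,
        species=opts.get("species"),
        bin_width=opts.get("bin_width", 0.1),
        origin=opts.get("origin", 0.0),
        bulk_density=opts.get("bulk_density"),
        bulk_window=tuple(opts["bulk_window"]) if opts.get("bulk_window") else None,
    )
    profile.to_dataframe().to_csv(outdir / "density_profile.csv", index=False)
    t_w = water_layer_thickness(profile)
    out = {
        "t_W": _q(t_w, "nm"),
        "bulk_density": _q(profile.bulk_density, "g_cm3"),
    }
    try:
        m1 = first_peak_mass(profile)
        out["M_1"] = _q(m1.mass_g_per_nm2, "g_nm2")
        out["first_peak"] = {
            "z0": _q(m1.region.z0, "nm"),
            "z1": _q(m1.region.z1, "nm"),
            "amplitude": _q(m1.region.amplitude, "g_cm3"),
        }
    except ValueError as exc:
        out["M_1"] = {"value": None, "units": "g_nm2", "note": str(exc)}
    return out


def _run_dynamics(cfg: RunConfig, outdir: Path) -> dict:
    opts = cfg.dynamics
    traj = read_trajectory(opts["trajectory"], opts.get("dialect", "extended_xyz"))
    curve = msd(
        traj,
        species=opts.get("species"),
        d_i=opts.get("d_i", 3),
        max_lag_fraction=opts.get("max_lag_fraction", 0.5),
    )
    curve.to_dataframe().to_csv(outdir / "msd.csv", index=False)
    fit_window = tuple(opts["fit_window"]) if opts.get("fit_window") else None
    res = diffusion_coefficient(curve, fit_window)
    return {
        "D": _q(res.D, "nm2_ps"),
        "D_SI": _q(res.D_m2_per_s, "m2_s"),
        "D_stderr": _q(res.stderr, "nm2_ps"),
    }


def _read_series(path) -> TemperatureSeries:
    df = pd.read_csv(path)
    return TemperatureSeries(
        times=df["time_ps"].to_numpy(), temperature=df["temperature_K"].to_numpy()
    )


def _run_thermal(cfg: RunConfig, outdir: Path) -> dict:
    opts = cfg.thermal
    out = {}
    if opts.get("series"):
        series = _read_series(opts["series"])
        fit = relaxation_time(series, T_env=opts.get("T_env", 300.0))
        sheet = GrapheneSheet(**opts.get("sheet", {}))
        g_k = kapitza_conductance(sheet, fit.tau)
        out["tau"] = _q(fit.tau, "ps")
        out["G_K"] = _q(g_k, "MW_m2_K")
        out["fit_rms_residual"] = _q(fit.rms_residual, "K")
    if opts.get("curve"):
        df = pd.read_csv(opts["curve"])
        curve = DeltaTCurve(
            power=df["power_GW_m2"].to_numpy(),
            delta_T=df["delta_T_K"].to_numpy(),
            stderr=df["stderr_K"].to_numpy() if "stderr_K" in df else None,
        )
        out["p_c"] = _q(
            critical_power(curve, opts.get("delta_T_c", 20.0)), "GW_m2"
        )
    return out


def _run_model(cfg: RunConfig, outdir: Path) -> dict:
    opts = cfg.model
    stack = InterfaceStack(**opts["stack"])
    sheet = GrapheneSheet(**opts.get("sheet", {}))
    p = opts.get("power", 1.0)
    out = {"power": _q(p, "GW_m2")}
    profile, summary = steady_state_profile(stack, p, bin_width=opts.get("bin_width", 0.1))
    profile.to_dataframe().to_csv(outdir / "model_steady_profile.csv", index=False)
    out["steady"] = {k: _q(v, "K") for k, v in summary.items()}
    t_end = opts.get("t_end_ps", 400.0)
    times = np.arange(0.0, t_end + 1e-9, opts.get("dt_ps", 1.0))
    series = transient_graphene_temperature(sheet, stack, p, times)
    series.to_dataframe().to_csv(outdir / "model_transient.csv", index=False)
    out["transient_plateau"] = _q(float(series.temperature[-1]), "K")
    out["p_c_lipid_surface"] = _q(
        predict_critical_power(stack, opts.get("delta_T_c", 20.0), "lipid_surface"),
        "GW_m2",
    )
    if opts.get("profile_csv"):
        df = pd.read_csv(opts["profile_csv"])
        prof = TemperatureProfile(
            z_bins=df["z_nm"].to_numpy(), temperature=df["temperature_K"].to_numpy()
        )
        res = fit_steady_parameters(
            prof, p, z_s=stack.z_s, delta=stack.delta, eta=stack.eta, T_e=stack.T_e
        )
        out["steady_fit"] = {
            "G_C": _q(res.G_C, "MW_m2_K"),
            "kappa_L": _q(res.kappa_L, "W_m_K"),
        }
    if opts.get("series_csv"):
        res = fit_transient(_read_series(opts["series_csv"]), sheet, p, eta=stack.eta)
        out["transient_fit"] = {"G_C": _q(res.G_C, "MW_m2_K")}
    return out


_RUNNERS = {
    "structure": _run_structure,
    "dynamics": _run_dynamics,
    "thermal": _run_thermal,
    "model": _run_model,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write summary.json to output_dir.

    Stage failures halt the run with context; artifacts from completed
    stages are retained.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {
        "nanoheat_version": __version__,
        "seed": int(config.seed),
        "config": {
            "stages": list(config.stages),
            "structure": config.structure,
            "dynamics": config.dynamics,
            "thermal": config.thermal,
            "model": config.model,
        },
        "results": {},
    }
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        log.info("stage %s: starting", stage)
        try:
            summary["results"][stage] = _RUNNERS[stage](config, outdir)
        except Exception as exc:
            (outdir / "summary.json").write_text(
                json.dumps(summary, indent=2, sort_keys=True)
            )
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s: done in %.2f s", stage, time.perf_counter() - t0)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
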