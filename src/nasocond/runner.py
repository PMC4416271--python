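"""Configuration, orchestration and tidy outputs.

A run takes a :class:`SimulationConfig` (YAML-serialisable), builds the
geometry, waveform, resistance network and transport solver, and writes a
directory of CSV time series plus a ``summary.json`` with partitioning
ratios, dehydration metrics, per-phase extrema and conservation audits. The
nasal-cycle experiment runs the same configuration twice with the congestion
pair swapped, to show the dehydrating role following the patent side.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .airflow import (
    BreathWaveform,
    apportion_flow,
    load_waveform,
    partition_for_geometry,
    tidal_waveform,
)
from .asl import ASLParameters, layer_heights
from .geometry import (
    NasalGeometry,
    SlitShapeParams,
    load_geometry,
    synthesize_geometry,
    write_geometry,
)
from .psychro import AmbientAir, air_transport_properties
from .transport import (
    CORE_TEMPERATURE_C,
    SimulationResult,
    WallModel,
    run_breath_cycles,
)

__all__ = [
    "GeometryConfig",
    "WaveformConfig",
    "SolverConfig",
    "SimulationConfig",
    "run",
    "nasal_cycle_experiment",
]

logger = logging.getLogger(__name__)


@dataclass
class GeometryConfig:
    source: str = "synth"            # "synth" | "file"
    path: str | None = None
    n_slices: int = 120
    slice_thickness_m: float = 0.78e-3
    congestion_left: float = 0.0
    congestion_right: float = 0.0
    jitter: float = 0.0
    gap_end_m: float = 1.4e-3
    gap_mid_m: float = 2.6e-3
    width_bulge: float = 0.3
    surface_area_m2: float = 0.01

    def build(self, rng: np.random.Generator | None = None) -> NasalGeometry:
        if self.source == "file":
            if not self.path:
                raise ValueError("geometry source 'file' requires a path")
            return load_geometry(self.path)
        if self.source != "synth":
            raise ValueError(f"unknown geometry source {self.source!r}")
        return synthesize_geometry(
            n_slices=self.n_slices,
            slice_thickness=self.slice_thickness_m,
            shape_params=SlitShapeParams(
                gap_end_m=self.gap_end_m,
                gap_mid_m=self.gap_mid_m,
                width_bulge=self.width_bulge,
                surface_area_m2=self.surface_area_m2,
            ),
            congestion_left=self.congestion_left,
            congestion_right=self.congestion_right,
            jitter=self.jitter,
            rng=rng,
        )


@dataclass
class WaveformConfig:
    tidal_volume_ml: float = 500.0
    breath_period_s: float = 5.0
    csv: str | None = None

    def build(self, density: float) -> BreathWaveform:
        if self.csv:
            return load_waveform(self.csv, density=density)
        return tidal_waveform(
            tidal_volume=self.tidal_volume_ml * 1e-6,
            breath_period=self.breath_period_s,
            density=density,
        )


@dataclass
class SolverConfig:
    dt_s: float = 1e-3
    n_cycles: int = 8
    spin_up_cycles: int = 3
    output_stride: int = 50


@dataclass
class SimulationConfig:
    ambient_temperature_c: float = 23.0
    ambient_relative_humidity: float = 0.45
    pressure_pa: float = 101325.0
    wall_anterior_c: float = 32.0
    wall_posterior_c: float = CORE_TEMPERATURE_C
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    waveform: WaveformConfig = field(default_factory=WaveformConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    asl: dict = field(default_factory=dict)  # overrides of ASLParameters fields
    seed: int = 0

    # -- construction helpers ----------------------------------------------

    def ambient(self) -> AmbientAir:
        return AmbientAir(
            temperature_c=self.ambient_temperature_c,
            relative_humidity=self.ambient_relative_humidity,
            pressure_pa=self.pressure_pa,
        )

    def wall(self) -> WallModel:
        return WallModel(anterior_c=self.wall_anterior_c, posterior_c=self.wall_posterior_c)

    def asl_params(self) -> ASLParameters:
        kwargs = dict(self.asl)
        if "supply_max" in kwargs:
            kwargs["supply_max"] = tuple(kwargs["supply_max"])
        return ASLParameters(**kwargs)

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key, sub in (
            ("geometry", GeometryConfig),
            ("waveform", WaveformConfig),
            ("solver", SolverConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _summarise(result: SimulationResult, extra: dict) -> dict:
    summary = {
        "partition_ratios": {
            "left": result.ratios.pr_left,
            "right": result.ratios.pr_right,
        },
        "dehydration_metrics": {
            side: {
                "min_he_um": m.min_he.tolist(),
                "severely_dehydrated_anterior_fraction":
                    m.severely_dehydrated_anterior_fraction,
                "time_at_zero_s": m.time_at_zero.tolist(),
            }
            for side, m in result.metrics.items()
        },
        "phase_extrema": result.phase_extrema,
        "max_audit_residual": max(
            abs(a[side][k])
            for a in result.cycle_audits
            for side in ("left", "right")
            for k in ("air", "asl")
        ),
        "dry_cap_events": result.dry_cap_events,
        "overflow_events": result.overflow_events,
    }
    summary.update(extra)
    return summary


def _write_timeseries(result: SimulationResult, out_dir: Path) -> None:
    rows = []
    asl_rows = []
    for side, sr in result.sides.items():
        xl = result.positions[side]
        nt, nk = sr.t_air.shape
        for it in range(nt):
            t = result.times[it]
            for k in range(nk):
                rows.append(
                    (side, k, xl[k], t, sr.t_air[it, k], sr.c_air[it, k], sr.he[it, k])
                )
    df = pd.DataFrame(
        rows,
        columns=["side", "k", "x_over_l", "time_s", "t_air_c", "c_air_kg_m3", "he_um"],
    )
    df.to_csv(out_dir / "results.csv", index=False, float_format="%.10g")


def _write_asl_series(
    result: SimulationResult, params: ASLParameters, out_dir: Path
) -> None:
    rows = []
    for side, sr in result.sides.items():
        xl = result.positions[side]
        heights = layer_heights(sr.he, params)
        for it in range(sr.he.shape[0]):
            t = result.times[it]
            for k in range(sr.he.shape[1]):
                rows.append(
                    (
                        side, k, xl[k], t, sr.he[it, k],
                        heights["pcl_height"][it, k],
                        bool(sr.he[it, k] <= 0.0),
                    )
                )
    pd.DataFrame(
        rows,
        columns=["side", "k", "x_over_l", "time_s", "he_um", "pcl_um", "flag_dry"],
    ).to_csv(out_dir / "asl_timeseries.csv", index=False, float_format="%.10g")


def _setup_run_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    pkg_logger = logging.getLogger("nasocond")
    if pkg_logger.getEffectiveLevel() > logging.INFO:
        pkg_logger.setLevel(logging.INFO)
    pkg_logger.addHandler(handler)
    return handler


def run(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Execute one simulation and write CSVs, summary JSON and a log.

    Deterministic for a given config (the seed drives synthetic-geometry
    jitter). Returns the summary dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(out)
    try:
        config.to_yaml(out / "config.yaml")

        ambient = config.ambient()
        logger.info(
            "ambient %.1f °C, RH %.0f%% -> inlet AH %.4g g/m³ (pressure %.0f Pa)",
            ambient.temperature_c, 100 * ambient.relative_humidity,
            1000 * ambient.absolute_humidity, ambient.pressure_pa,
        )

        rng = np.random.default_rng(config.seed)
        geometry = config.geometry.build(rng=rng)
        write_geometry(geometry, out / "geometry.csv")
        logger.info(
            "geometry: %d slices/side, surface area L=%.1f cm² R=%.1f cm², "
            "max effective gap %.2f mm",
            len(geometry.left),
            1e4 * geometry.surface_area("left"), 1e4 * geometry.surface_area("right"),
            1e3 * max(geometry.effective_gaps("left").max(),
                      geometry.effective_gaps("right").max()),
        )

        film_t = 0.5 * (ambient.temperature_c + CORE_TEMPERATURE_C)
        props = air_transport_properties(film_t, ambient.pressure_pa)
        ratios, resistance = partition_for_geometry(geometry, props)
        logger.info(
            "resistance sums L=%.4g R=%.4g m·s/kg, total %.4g; PR = (%.3f, %.3f) "
            "(constant over the breath: laminar resistance is flow-independent)",
            resistance.sum_left, resistance.sum_right, resistance.r_total,
            ratios.pr_left, ratios.pr_right,
        )

        inlet_density = air_transport_properties(
            ambient.temperature_c, ambient.pressure_pa
        ).density
        waveform = config.waveform.build(density=inlet_density)
        flows = apportion_flow(waveform, ratios)
        assert np.allclose(flows["left"] + flows["right"], waveform.mass_flow)

        asl_params = config.asl_params()
        wall = config.wall()
        result = run_breath_cycles(
            geometry, waveform, ratios, wall, ambient, asl_params,
            n_cycles=config.solver.n_cycles,
            dt=config.solver.dt_s,
            spin_up_cycles=config.solver.spin_up_cycles,
            output_stride=config.solver.output_stride,
            air_props=props,
        )

        _write_timeseries(result, out)
        _write_asl_series(result, asl_params, out)

        summary = _summarise(
            result,
            extra={
                "inlet_absolute_humidity_g_m3": 1000 * ambient.absolute_humidity,
                "resistance": dataclasses.asdict(resistance),
                "surface_area_cm2": {
                    s: 1e4 * geometry.surface_area(s) for s in ("left", "right")
                },
                "peak_mass_flow_kg_s": waveform.peak_mass_flow,
                "congestion": {
                    "left": config.geometry.congestion_left,
                    "right": config.geometry.congestion_right,
                },
            },
        )
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        logger.info("run complete: %s", out)
        return summary
    finally:
        logging.getLogger("nasocond").removeHandler(handler)
        handler.close()


def nasal_cycle_experiment(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Run the congestion pair and its swap; compare the two states.

    The patent (lower-congestion) side should carry PR > 0.5 and show the
    deeper ASL dehydration in both states; swapping the pair mirrors the
    per-side metrics (pure relabelling).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cl, cr = config.geometry.congestion_left, config.geometry.congestion_right
    if cl == cr:
        logger.warning(
            "symmetric congestion pair (%.2f, %.2f): nasal-cycle experiment "
            "is degenerate", cl, cr,
        )

    swapped = SimulationConfig.from_dict(config.to_dict())
    swapped.geometry.congestion_left = cr
    swapped.geometry.congestion_right = cl

    summary_a = run(config, out / "state_a")
    summary_b = run(swapped, out / "state_b")

    def patent(summary: dict) -> str:
        pr = summary["partition_ratios"]
        return "left" if pr["left"] >= pr["right"] else "right"

    mirror = {}
    for key_a, key_b in (("left", "right"), ("right", "left")):
        ma = summary_a["dehydration_metrics"][key_a]
        mb = summary_b["dehydration_metrics"][key_b]
        a = np.array(ma["min_he_um"])
        b = np.array(mb["min_he_um"])
        mirror[f"{key_a}_vs_{key_b}_min_he_max_abs_diff"] = float(np.abs(a - b).max())

    comparison = {
        "state_a": {
            "congestion": (cl, cr),
            "partition_ratios": summary_a["partition_ratios"],
            "patent_side": patent(summary_a),
            "anterior_fraction": {
                s: summary_a["dehydration_metrics"][s][
                    "severely_dehydrated_anterior_fraction"
                ]
                for s in ("left", "right")
            },
        },
        "state_b": {
            "congestion": (cr, cl),
            "partition_ratios": summary_b["partition_ratios"],
            "patent_side": patent(summary_b),
            "anterior_fraction": {
                s: summary_b["dehydration_metrics"][s][
                    "severely_dehydrated_anterior_fraction"
                ]
                for s in ("left", "right")
            },
        },
        "role_swap_mirror": mirror,
    }
    with open(out / "comparison.json", "w") as fh:
        json.dump(comparison, fh, indent=2, sort_keys=True, default=_json_default)
    return comparison
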