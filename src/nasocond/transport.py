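"""Transient per-segment air temperature and vapour-concentration solver.

Each passage is a chain of well-mixed lumps exchanging heat and water with a
prescribed-temperature wall whose surface is the ASL. Numerics: explicit
first-order upwind advection (conservative, constant volumetric flow along
the passage) plus forward-Euler wall exchange, sub-stepped so that the
combined advection + exchange update coefficient stays below one (this also
enforces Courant number ≤ 1).

Sign conventions: mass flow > 0 is inhalation (anterior → posterior). The
wall vapour flux j = h_m·(C_sat(T_w) − C_a) evaporates from the ASL when
positive and condenses onto it when negative; any supersaturation of the air
with respect to its own temperature is clipped to the local ASL as
condensate. Evaporative enthalpy is drawn from the mucosal reservoir, not
from the air energy balance (prescribed-wall simplification).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import asl as asl_mod
from .airflow import BreathWaveform, PartitionRatios
from .asl import ASLParameters, dehydration_metrics, update_asl
from .geometry import NasalGeometry, edge_positions, normalized_positions
from .psychro import (
    AirProperties,
    AmbientAir,
    air_transport_properties,
    saturation_vapour_density,
)

__all__ = [
    "NU_PARALLEL_PLATES",
    "WallModel",
    "TransferCoefficients",
    "AirState",
    "SolverError",
    "PassageModel",
    "SideResult",
    "SimulationResult",
    "transfer_coefficients",
    "run_breath_cycles",
]

#: laminar fully developed Nusselt number between parallel plates at
#: constant wall temperature
NU_PARALLEL_PLATES = 7.54

CORE_TEMPERATURE_C = 37.0


class SolverError(RuntimeError):
    """Raised when the stability sub-step limit cannot be satisfied."""


@dataclass(frozen=True)
class WallModel:
    """Prescribed wall/ASL surface temperature, linear in X/L.

    Defaults run from 32 °C at the anterior nasal valve to core temperature
    (37 °C) at the choanae, constant in time. The anterior value is a tunable
    stand-in, not a measured quantity.
    """

    anterior_c: float = 32.0
    posterior_c: float = CORE_TEMPERATURE_C

    def __post_init__(self) -> None:
        for v in (self.anterior_c, self.posterior_c):
            if not 20.0 <= v <= 40.0:
                raise ValueError(f"wall temperature {v} °C outside [20, 40] °C")

    def temperatures(self, x_over_l) -> np.ndarray:
        x = np.asarray(x_over_l, dtype=float)
        return self.anterior_c + (self.posterior_c - self.anterior_c) * x


@dataclass(frozen=True)
class TransferCoefficients:
    """Per-segment heat (W/m²·K) and mass (m/s) transfer coefficients."""

    h: np.ndarray
    h_m: np.ndarray


def transfer_coefficients(dh, air_props: AirProperties) -> TransferCoefficients:
    """Laminar parallel-plate coefficients for hydraulic diameter(s) ``dh``.

    h = Nu·k_air/Dh with Nu = 7.54 (constant wall temperature); the mass
    transfer coefficient follows from the Chilton–Colburn analogy,
    h_m = h/(ρ·c_p·Le^(2/3)) with Le = α/D_v.
    """
    d = np.asarray(dh, dtype=float)
    if np.any(d <= 0):
        raise ValueError("hydraulic diameter must be positive")
    h = NU_PARALLEL_PLATES * air_props.thermal_conductivity / d
    le = air_props.lewis_number
    h_m = h / (air_props.density * air_props.specific_heat * le ** (2.0 / 3.0))
    return TransferCoefficients(h=np.atleast_1d(h), h_m=np.atleast_1d(h_m))


@dataclass
class AirState:
    """Per-segment air temperature (°C) and vapour concentration (kg/m³)."""

    t_air: np.ndarray
    c_air: np.ndarray

    def __post_init__(self) -> None:
        self.t_air = np.asarray(self.t_air, dtype=float)
        self.c_air = np.asarray(self.c_air, dtype=float)
        if np.any(self.c_air < 0):
            raise ValueError("vapour concentration must be non-negative")


class PassageModel:
    """One nasal passage: geometry arrays, wall boundary, and mutable state.

    ``advance`` integrates the passage over an interval at a constant mass
    flow, sub-stepping to respect the explicit stability bound. Water
    bookkeeping accumulates between calls to :meth:`reset_audit`.
    """

    def __init__(
        self,
        geometry: NasalGeometry,
        side: str,
        wall: WallModel,
        ambient: AmbientAir,
        asl_params: ASLParameters,
        air_props: AirProperties | None = None,
        core_temperature_c: float = CORE_TEMPERATURE_C,
        vapour_exchange: bool = True,
        cfl_target: float = 0.9,
        max_substeps: int = 100_000,
    ) -> None:
        self.side = side
        self.asl_params = asl_params
        self.vapour_exchange = vapour_exchange
        self.cfl_target = cfl_target
        self.max_substeps = max_substeps

        self.props = air_props or air_transport_properties(30.0, ambient.pressure_pa)
        self.rho = self.props.density
        self.cp = self.props.specific_heat

        self.area = geometry.areas(side)
        self.length = geometry.lengths(side)
        self.perimeter = geometry.perimeters(side)
        self.vol = self.area * self.length
        self.surf = self.perimeter * self.length
        self.x_over_l = normalized_positions(geometry)[side]
        self.edge_x_over_l = edge_positions(geometry)[side]
        dh = 4.0 * self.area / self.perimeter

        self.wall_t = wall.temperatures(self.x_over_l)
        self.csat_wall = saturation_vapour_density(self.wall_t)
        coeffs = transfer_coefficients(dh, self.props)
        self.h = coeffs.h
        self.h_m = coeffs.h_m

        self.ambient_t = ambient.temperature_c
        self.ambient_c = ambient.absolute_humidity
        self.core_t = core_temperature_c
        self.core_c = saturation_vapour_density(core_temperature_c)

        # exchange update rates, 1/s (stability bound contributions)
        heat_rate = self.h * self.surf / (self.rho * self.cp * self.vol)
        mass_rate = self.h_m * self.surf / self.vol if vapour_exchange else 0.0
        self._exch_rate = np.maximum(heat_rate, mass_rate)

        # initial state: air in equilibrium with the wall, ASL fully hydrated
        self.air = AirState(t_air=self.wall_t.copy(), c_air=self.csat_wall.copy())
        self.he = np.full(self.area.shape, asl_params.he_max)

        self.he_min = self.he.copy()
        self.dry_cap_events = 0
        self.overflow_events = 0
        self.reset_audit()

    # -- bookkeeping --------------------------------------------------------

    def air_water_mass(self) -> float:
        """Water vapour stored in the passage air, kg."""
        return float((self.air.c_air * self.vol).sum())

    def asl_water_mass(self) -> float:
        """Water stored in the ASL, kg."""
        return float(
            (self.he * 1e-6 * asl_mod.WATER_DENSITY * self.surf).sum()
        )

    def reset_audit(self) -> None:
        self.audit = {
            "air_storage_start": self.air_water_mass(),
            "asl_storage_start": self.asl_water_mass(),
            "boundary_in": 0.0,
            "boundary_out": 0.0,
            "wall_to_air": 0.0,
            "supply": 0.0,
            "reabsorption": 0.0,
            "overflow": 0.0,
        }

    def audit_residuals(self) -> dict[str, float]:
        """Relative water-conservation residuals since the last reset.

        ``air``: Δ(air vapour) − boundary net − wall-to-air transfer.
        ``asl``: Δ(ASL store) − supply + wall-to-air + reabsorption + overflow.
        Both normalised by the gross water turnover of the interval.
        """
        a = self.audit
        d_air = self.air_water_mass() - a["air_storage_start"]
        d_asl = self.asl_water_mass() - a["asl_storage_start"]
        res_air = d_air - (a["boundary_in"] - a["boundary_out"]) - a["wall_to_air"]
        res_asl = d_asl - a["supply"] + a["wall_to_air"] + a["reabsorption"] + a["overflow"]
        scale = max(
            a["boundary_in"] + a["boundary_out"] + abs(a["wall_to_air"])
            + a["supply"] + a["air_storage_start"] + a["asl_storage_start"],
            1e-30,
        )
        return {"air": res_air / scale, "asl": res_asl / scale}

    # -- integration --------------------------------------------------------

    def advance(self, mass_flow: float, dt: float) -> None:
        """Integrate the passage over ``dt`` at constant mass flow (kg/s)."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        q = mass_flow / self.rho  # signed volumetric flow, m³/s
        rate = self._exch_rate + abs(q) / self.vol
        rate_max = float(rate.max())
        n_sub = max(1, int(np.ceil(dt * rate_max / self.cfl_target)))
        if n_sub > self.max_substeps:
            raise SolverError(
                f"stability requires {n_sub} sub-steps for dt={dt}s "
                f"(limit {self.max_substeps}); reduce dt or coarsen the flow"
            )
        dts = dt / n_sub
        for _ in range(n_sub):
            self._substep(q, dts)

    def _substep(self, q: float, dts: float) -> None:
        t = self.air.t_air
        c = self.air.c_air

        if q > 0:  # inhalation: anterior → posterior
            t_up = np.concatenate(([self.ambient_t], t[:-1]))
            c_up = np.concatenate(([self.ambient_c], c[:-1]))
            c_inlet, c_outlet = self.ambient_c, c[-1]
        elif q < 0:  # exhalation: posterior → anterior
            t_up = np.concatenate((t[1:], [self.core_t]))
            c_up = np.concatenate((c[1:], [self.core_c]))
            c_inlet, c_outlet = self.core_c, c[0]
        if q != 0.0:
            qa = abs(q)
            adv = qa * dts / self.vol
            t = t + adv * (t_up - t)
            c = c + adv * (c_up - c)
            self.audit["boundary_in"] += qa * c_inlet * dts
            self.audit["boundary_out"] += qa * c_outlet * dts

        # convective heating against the prescribed wall
        t = t + dts * self.h * self.surf * (self.wall_t - t) / (
            self.rho * self.cp * self.vol
        )

        if self.vapour_exchange:
            j = self.h_m * (self.csat_wall - c)
            upd = update_asl(self.he, j, dts, self.asl_params)
            self.he = upd.he
            c = c + upd.delivered_flux * self.surf * dts / self.vol
            self._log_asl(upd, dts)

            # supersaturation clip: excess condenses onto the local ASL
            xs = np.maximum(c - saturation_vapour_density(t), 0.0)
            if np.any(xs > 0):
                e2 = -xs * self.vol / (self.surf * dts)
                upd2 = update_asl(self.he, e2, dts, self.asl_params)
                self.he = upd2.he
                c = c - xs
                self._log_asl(upd2, dts)

            np.minimum(self.he_min, self.he, out=self.he_min)

        self.air.t_air = t
        self.air.c_air = c

    def _log_asl(self, upd, dts: float) -> None:
        self.audit["wall_to_air"] += float((upd.delivered_flux * self.surf).sum()) * dts
        self.audit["supply"] += float((upd.supply_flux * self.surf).sum()) * dts
        self.audit["reabsorption"] += float((upd.reabsorption_flux * self.surf).sum()) * dts
        self.audit["overflow"] += float((upd.overflow_flux * self.surf).sum()) * dts
        self.dry_cap_events += int(upd.dry_capped.sum())
        self.overflow_events += int(upd.overflowed.sum())


# ---------------------------------------------------------------------------
# Breath-cycle driver


@dataclass
class SideResult:
    """Recorded state history of one passage, shape (n_times, n_segments)."""

    t_air: np.ndarray
    c_air: np.ndarray
    he: np.ndarray


@dataclass
class SimulationResult:
    times: np.ndarray                 # recorded instants, s
    mass_flow: np.ndarray             # total tidal mass flow at those instants
    ratios: PartitionRatios
    positions: dict[str, np.ndarray]       # midpoint X/L per side
    edge_positions: dict[str, np.ndarray]  # posterior-edge X/L per side
    wall_t: dict[str, np.ndarray]
    sides: dict[str, SideResult]
    cycle_audits: list[dict]
    metrics: dict[str, asl_mod.DehydrationMetrics] = field(default_factory=dict)
    phase_extrema: dict = field(default_factory=dict)
    dry_cap_events: dict[str, int] = field(default_factory=dict)
    overflow_events: dict[str, int] = field(default_factory=dict)

    @property
    def inhalation_mask(self) -> np.ndarray:
        return self.mass_flow > 0


def run_breath_cycles(
    geometry: NasalGeometry,
    waveform: BreathWaveform,
    ratios: PartitionRatios,
    wall: WallModel,
    ambient: AmbientAir,
    asl_params: ASLParameters,
    n_cycles: int = 8,
    dt: float = 1e-3,
    spin_up_cycles: int = 3,
    output_stride: int = 10,
    air_props: AirProperties | None = None,
    core_temperature_c: float = CORE_TEMPERATURE_C,
) -> SimulationResult:
    """Simulate ``n_cycles`` breaths over both passages.

    States are recorded every ``output_stride`` steps; the first
    ``spin_up_cycles`` cycles are integrated but excluded from the recorded
    history, metrics and extrema. Water-conservation audits are closed at
    every cycle boundary.
    """
    if n_cycles <= spin_up_cycles:
        raise ValueError("n_cycles must exceed spin_up_cycles")
    passages = {
        side: PassageModel(
            geometry, side, wall, ambient, asl_params,
            air_props=air_props, core_temperature_c=core_temperature_c,
        )
        for side in ("left", "right")
    }
    pr = {"left": ratios.pr_left, "right": ratios.pr_right}

    steps_per_cycle = max(1, round(waveform.period / dt))
    dt_eff = waveform.period / steps_per_cycle

    rec_times, rec_flow = [], []
    rec = {s: {"t_air": [], "c_air": [], "he": []} for s in passages}
    cycle_audits: list[dict] = []

    for cycle in range(n_cycles):
        for p in passages.values():
            p.reset_audit()
        for i in range(steps_per_cycle):
            t_mid = cycle * waveform.period + (i + 0.5) * dt_eff
            m_total = float(waveform.flow_at(t_mid))
            for side, p in passages.items():
                p.advance(pr[side] * m_total, dt_eff)
            if cycle >= spin_up_cycles and (i + 1) % output_stride == 0:
                t_now = cycle * waveform.period + (i + 1) * dt_eff
                rec_times.append(t_now)
                rec_flow.append(float(waveform.flow_at(t_now)))
                for side, p in passages.items():
                    rec[side]["t_air"].append(p.air.t_air.copy())
                    rec[side]["c_air"].append(p.air.c_air.copy())
                    rec[side]["he"].append(p.he.copy())
        cycle_audits.append(
            {side: p.audit_residuals() for side, p in passages.items()}
            | {"cycle": cycle}
        )

    times = np.array(rec_times)
    flow = np.array(rec_flow)
    sides = {
        s: SideResult(
            t_air=np.array(rec[s]["t_air"]),
            c_air=np.array(rec[s]["c_air"]),
            he=np.array(rec[s]["he"]),
        )
        for s in passages
    }

    result = SimulationResult(
        times=times,
        mass_flow=flow,
        ratios=ratios,
        positions={s: p.x_over_l for s, p in passages.items()},
        edge_positions={s: p.edge_x_over_l for s, p in passages.items()},
        wall_t={s: p.wall_t for s, p in passages.items()},
        sides=sides,
        cycle_audits=cycle_audits,
        dry_cap_events={s: p.dry_cap_events for s, p in passages.items()},
        overflow_events={s: p.overflow_events for s, p in passages.items()},
    )

    inhaling = flow > 0
    for s, p in passages.items():
        result.metrics[s] = dehydration_metrics(
            sides[s].he, p.edge_x_over_l, times=times, inhalation_mask=inhaling
        )
    result.phase_extrema = _phase_extrema(result)
    return result


def _phase_extrema(result: SimulationResult) -> dict:
    """Min/max of each field per breath phase (post spin-up records)."""
    out: dict = {}
    for phase, mask in (
        ("inhalation", result.inhalation_mask),
        ("exhalation", ~result.inhalation_mask),
    ):
        out[phase] = {}
        for side, sr in result.sides.items():
            if not mask.any():
                continue
            out[phase][side] = {
                "t_air_min": float(sr.t_air[mask].min()),
                "t_air_max": float(sr.t_air[mask].max()),
                "c_air_min": float(sr.c_air[mask].min()),
                "c_air_max": float(sr.c_air[mask].max()),
                "he_min": float(sr.he[mask].min()),
                "he_max": float(sr.he[mask].max()),
            }
    return out
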