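"""Laminar resistance network and tidal-flow partitioning.

The passage is a series of narrow-gap lumps, each modelled as flow between
closely spaced parallel plates (friction factor f = 24/Re). Segment head loss
follows Darcy–Weisbach; the resulting specific resistance per lump is
R = 3·μ·P²·l / (4·ρ²·A³·g), independent of flow rate, so the two passages
combine as a linear parallel network and the partitioning ratios are constant
over a breath at fixed congestion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import AirwaySegment, NasalGeometry
from .psychro import AirProperties

__all__ = [
    "GRAVITY",
    "PartitionRatios",
    "TotalResistance",
    "BreathWaveform",
    "reynolds_number",
    "friction_factor",
    "head_loss",
    "specific_resistance",
    "segment_resistances",
    "total_resistance",
    "partition_ratios",
    "partition_for_geometry",
    "tidal_waveform",
    "load_waveform",
    "apportion_flow",
    "head_to_pressure",
]

logger = logging.getLogger(__name__)

GRAVITY = 9.81  # m/s²

#: default Reynolds number above which the laminar assumption is flagged
LAMINAR_RE_THRESHOLD = 2000.0


def _perimeter_of(segment) -> float:
    return segment.perimeter if isinstance(segment, AirwaySegment) else float(segment)


def reynolds_number(mass_flow, segment, viscosity: float):
    """Duct Reynolds number Re_d = 4·ṁ/(P·μ).

    Equivalent to ρ·V·Dh/μ with V = ṁ/(ρA) and Dh = 4A/P. ``segment`` may be
    an :class:`AirwaySegment` or a bare perimeter in m. Use the magnitude of
    ``mass_flow`` during exhalation.
    """
    p = _perimeter_of(segment)
    m = np.abs(np.asarray(mass_flow, dtype=float))
    out = 4.0 * m / (p * viscosity)
    return float(out) if np.isscalar(mass_flow) else out


def friction_factor(re, laminar_threshold: float = LAMINAR_RE_THRESHOLD):
    """Parallel-plate laminar friction factor f = 24/Re.

    Logs a warning when ``re`` exceeds the laminar threshold, since the model
    assumes laminar flow throughout the passage.
    """
    r = np.asarray(re, dtype=float)
    if np.any(r <= 0):
        raise ValueError("Reynolds number must be positive")
    if np.any(r > laminar_threshold):
        logger.warning(
            "Reynolds number %s exceeds laminar threshold %g; "
            "laminar friction law extrapolated",
            np.max(r), laminar_threshold,
        )
    out = 24.0 / r
    return float(out) if np.isscalar(re) else out


def head_loss(f, length: float, velocity, dh):
    """Darcy–Weisbach head loss h_f = f·l·V²/(2·g·Dh), m of head."""
    d = np.asarray(dh, dtype=float)
    if length <= 0 or np.any(d <= 0):
        raise ValueError("length and hydraulic diameter must be positive")
    v = np.asarray(velocity, dtype=float)
    out = np.asarray(f, dtype=float) * length * v**2 / (2.0 * GRAVITY * d)
    return float(out) if np.isscalar(f) and np.isscalar(velocity) else out


def specific_resistance(segment: AirwaySegment, viscosity: float, density: float) -> float:
    """Segment resistance R = 3·μ·P²·l/(4·ρ²·A³·g), head per unit mass flow.

    Flow-independent (laminar linearity): equals head_loss/ṁ for any ṁ > 0.
    """
    return (
        3.0 * viscosity * segment.perimeter**2 * segment.length
        / (4.0 * density**2 * segment.area**3 * GRAVITY)
    )


def segment_resistances(
    geometry: NasalGeometry, side: str, viscosity: float, density: float
) -> np.ndarray:
    a = geometry.areas(side)
    p = geometry.perimeters(side)
    l = geometry.lengths(side)
    return 3.0 * viscosity * p**2 * l / (4.0 * density**2 * a**3 * GRAVITY)


@dataclass(frozen=True)
class TotalResistance:
    """Series sums per side and their parallel combination."""

    sum_left: float
    sum_right: float
    r_total: float


def total_resistance(r_left, r_right) -> TotalResistance:
    """Series-sum each side; combine the sides in parallel.

    1/R_total = 1/ΣR_left + 1/ΣR_right, so R_total < min of the side sums.
    """
    rl = np.asarray(r_left, dtype=float)
    rr = np.asarray(r_right, dtype=float)
    if rl.size == 0 or rr.size == 0:
        raise ValueError("each side needs at least one segment resistance")
    if np.any(rl <= 0) or np.any(rr <= 0):
        raise ValueError("segment resistances must be positive")
    sum_l = float(rl.sum())
    sum_r = float(rr.sum())
    r_total = 1.0 / (1.0 / sum_l + 1.0 / sum_r)
    return TotalResistance(sum_left=sum_l, sum_right=sum_r, r_total=r_total)


@dataclass(frozen=True)
class PartitionRatios:
    """Fraction of total tidal mass flow carried by each passage."""

    pr_left: float
    pr_right: float

    def __post_init__(self) -> None:
        if not (0.0 < self.pr_left < 1.0 and 0.0 < self.pr_right < 1.0):
            raise ValueError("partition ratios must lie in (0, 1)")
        if abs(self.pr_left + self.pr_right - 1.0) > 1e-12:
            raise ValueError("partition ratios must sum to 1")

    def swapped(self) -> "PartitionRatios":
        return PartitionRatios(pr_left=self.pr_right, pr_right=self.pr_left)


def partition_ratios(sum_left: float, sum_right: float) -> PartitionRatios:
    """PR_side = R_total/ΣR_side; the lower-resistance side carries more flow.

    PR_left + PR_right = 1 is an algebraic identity of the parallel network.
    """
    if sum_left <= 0 or sum_right <= 0:
        raise ValueError("side resistance sums must be positive")
    # R_total/ΣR_side expanded to avoid a needless division round-trip
    pr_left = sum_right / (sum_left + sum_right)
    pr_right = sum_left / (sum_left + sum_right)
    return PartitionRatios(pr_left=pr_left, pr_right=pr_right)


def partition_for_geometry(
    geometry: NasalGeometry, air_props: AirProperties
) -> tuple[PartitionRatios, TotalResistance]:
    """Resistance network and partitioning ratios of a two-passage geometry."""
    mu = air_props.dynamic_viscosity
    rho = air_props.density
    tot = total_resistance(
        segment_resistances(geometry, "left", mu, rho),
        segment_resistances(geometry, "right", mu, rho),
    )
    return partition_ratios(tot.sum_left, tot.sum_right), tot


def head_to_pressure(head_m: float, density: float) -> float:
    """Convert head (m) to pressure drop (Pa): Δp = ρ·g·h."""
    return density * GRAVITY * head_m


# ---------------------------------------------------------------------------
# Tidal waveform


@dataclass(frozen=True)
class BreathWaveform:
    """One period of the tidal mass-flow trace (positive = inhalation)."""

    times: np.ndarray       # s, spanning [0, period]
    mass_flow: np.ndarray   # kg/s
    period: float           # s
    tidal_volume: float     # m³
    density: float          # kg/m³ used for the mass↔volume conversion

    def flow_at(self, t) -> np.ndarray:
        """Mass flow at time(s) ``t``, periodic extension."""
        tt = np.mod(np.asarray(t, dtype=float), self.period)
        out = np.interp(tt, self.times, self.mass_flow)
        return float(out) if np.isscalar(t) else out

    def inhaled_volume(self) -> float:
        """Volume drawn in over the inhalation phase, m³."""
        q = np.maximum(self.mass_flow, 0.0) / self.density
        return float(np.trapezoid(q, self.times))

    def net_volume(self) -> float:
        """Signed volume over one period (≈0 for balanced breathing), m³."""
        return float(np.trapezoid(self.mass_flow / self.density, self.times))

    @property
    def peak_mass_flow(self) -> float:
        return float(np.abs(self.mass_flow).max())


def tidal_waveform(
    tidal_volume: float = 500e-6,
    breath_period: float = 5.0,
    density: float = 1.2,
    n_samples: int = 2001,
) -> BreathWaveform:
    """Sinusoidal tidal trace ṁ(t) = (π·Vt·ρ/Tp)·sin(2πt/Tp).

    The inhalation phase occupies the first half-period and integrates to
    exactly the tidal volume; exhalation mirrors it.
    """
    if tidal_volume <= 0 or breath_period <= 0:
        raise ValueError("tidal volume and breath period must be positive")
    t = np.linspace(0.0, breath_period, n_samples)
    peak = np.pi * tidal_volume * density / breath_period
    m = peak * np.sin(2.0 * np.pi * t / breath_period)
    return BreathWaveform(
        times=t, mass_flow=m, period=breath_period,
        tidal_volume=tidal_volume, density=density,
    )


def load_waveform(
    path, density: float = 1.2, imbalance_tol: float = 0.01
) -> BreathWaveform:
    """Read a measured trace CSV (columns ``time_s,mass_flow_kg_s``).

    Rejects traces whose net volume over the period exceeds ``imbalance_tol``
    of the inhaled volume.
    """
    df = pd.read_csv(path)
    for col in ("time_s", "mass_flow_kg_s"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    m = df["mass_flow_kg_s"].to_numpy(dtype=float)
    if t.size < 3 or np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    period = float(t[-1] - t[0])
    wf = BreathWaveform(
        times=t - t[0], mass_flow=m, period=period,
        tidal_volume=float(np.trapezoid(np.maximum(m, 0) / density, t)),
        density=density,
    )
    if wf.tidal_volume <= 0:
        raise ValueError(f"{path}: trace has no inhalation phase")
    if abs(wf.net_volume()) > imbalance_tol * wf.tidal_volume:
        raise ValueError(
            f"{path}: inhaled/exhaled volume imbalance "
            f"{wf.net_volume() / wf.tidal_volume:.2%} exceeds {imbalance_tol:.0%}"
        )
    return wf


def apportion_flow(
    waveform: BreathWaveform, ratios: PartitionRatios
) -> dict[str, np.ndarray]:
    """Split the tidal trace between the passages at every instant.

    Each side carries total × PR_side; the sides sum to the input trace
    exactly.
    """
    return {
        "left": ratios.pr_left * waveform.mass_flow,
        "right": ratios.pr_right * waveform.mass_flow,
    }
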