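"""Airway-surface-liquid (ASL) hydration ledger.

The ASL is a two-layer film — mucus gel on top of the periciliary layer
(PCL). Its hydration state is tracked as a scalar water-equivalent height
``he`` per segment: the depth of water (per unit area) that can still be
withdrawn before mucociliary transport ceases. Fully hydrated he = he_max
(default 10 μm); severely dehydrated he = 0.

The layer-height construction: over the full dehydration range the PCL loses
``pcl_span`` (4 μm) of height while the mucus — with half the osmotic bulk
modulus — loses twice that (8 μm), for a total height span of 12 μm; the 85%
water volume fraction of that span gives he_max.

Supply and reabsorption are instantaneous per-segment flux caps. The printed
supply maximum (7.9 g/cm²·hr) is carried with its unit in the configuration
so smaller effective caps (e.g. mg/cm²·hr) can be substituted without code
change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ASLParameters",
    "ASLState",
    "ASLUpdate",
    "DehydrationMetrics",
    "derive_spans",
    "layer_heights",
    "update_asl",
    "dehydration_metrics",
    "areal_flux_to_si",
]

WATER_DENSITY = 1000.0  # kg/m³
_UM_TO_M = 1e-6

#: supported units for the supply/reabsorption caps → kg/(m²·s) factors
_FLUX_UNITS = {
    "kg/m2/s": 1.0,
    "g/m2/s": 1e-3,
    "g/cm2/hr": 1e-3 / (1e-4 * 3600.0),
    "mg/cm2/hr": 1e-6 / (1e-4 * 3600.0),
    "um/s": _UM_TO_M * WATER_DENSITY,  # water-height rate
}


def areal_flux_to_si(value: float, unit: str) -> float:
    """Convert an areal water flux to kg/(m²·s)."""
    key = unit.replace(" ", "").replace("·", "").replace("^", "").lower()
    key = key.replace("hr", "hr").replace("cm²", "cm2").replace("m²", "m2")
    if key not in _FLUX_UNITS:
        raise ValueError(f"unknown areal-flux unit {unit!r}; known: {sorted(_FLUX_UNITS)}")
    return value * _FLUX_UNITS[key]


def derive_spans(pcl_span: float, modulus_ratio: float, water_fraction: float) -> dict:
    """Layer-height spans over the full dehydration range.

    The mucus osmotic bulk modulus is ``1/modulus_ratio`` of the PCL's, so the
    mucus height change is ``modulus_ratio × pcl_span``; the total ASL height
    variation is their sum, and the water-equivalent span he_max is the water
    volume fraction of the total, rounded to the nearest micrometre.
    """
    if pcl_span <= 0 or modulus_ratio <= 0 or water_fraction <= 0:
        raise ValueError("spans, ratio and water fraction must be positive")
    if water_fraction > 1:
        raise ValueError("water_fraction must be <= 1")
    mucus_span = modulus_ratio * pcl_span
    total = pcl_span + mucus_span
    he_max = round(water_fraction * total)
    return {"mucus_span": mucus_span, "total_height_span": total, "he_max": he_max}


@dataclass(frozen=True)
class ASLParameters:
    """Hydration-ledger parameters (heights in μm, caps as (value, unit))."""

    pcl_span: float = 4.0
    modulus_ratio: float = 2.0
    water_fraction: float = 0.85
    pcl_hydrated_height: float = 7.5
    supply_max: tuple[float, str] = (7.9, "g/cm2/hr")
    reabsorption_ratio: float = 3.5
    # derived
    mucus_span: float = field(init=False)
    total_height_span: float = field(init=False)
    he_max: float = field(init=False)

    def __post_init__(self) -> None:
        spans = derive_spans(self.pcl_span, self.modulus_ratio, self.water_fraction)
        object.__setattr__(self, "mucus_span", spans["mucus_span"])
        object.__setattr__(self, "total_height_span", spans["total_height_span"])
        object.__setattr__(self, "he_max", float(spans["he_max"]))
        if self.pcl_hydrated_height <= self.pcl_span:
            raise ValueError("hydrated PCL height must exceed its dehydration span")
        if self.reabsorption_ratio <= 0:
            raise ValueError("reabsorption_ratio must be positive")

    @property
    def supply_max_si(self) -> float:
        """Maximum mucosal supply flux, kg/(m²·s)."""
        return areal_flux_to_si(*self.supply_max)

    @property
    def reabsorption_max(self) -> tuple[float, str]:
        """Maximum reabsorption flux = supply_max / reabsorption_ratio."""
        return (self.supply_max[0] / self.reabsorption_ratio, self.supply_max[1])

    @property
    def reabsorption_max_si(self) -> float:
        return self.supply_max_si / self.reabsorption_ratio


@dataclass
class ASLState:
    """Per-segment water-equivalent heights, μm."""

    he: np.ndarray
    he_max: float

    def __post_init__(self) -> None:
        self.he = np.asarray(self.he, dtype=float)
        if np.any(self.he < 0) or np.any(self.he > self.he_max + 1e-12):
            raise ValueError("he must lie in [0, he_max]")

    @property
    def severely_dehydrated(self) -> np.ndarray:
        return self.he <= 0.0


def layer_heights(he, params: ASLParameters) -> dict:
    """PCL height and mucus height change at water-equivalent height ``he``.

    Linear interpolation between the fully hydrated state (PCL at its
    hydrated height, mucus unchanged) and severe dehydration (PCL down by
    its span, mucus down by its span).
    """
    h = np.asarray(he, dtype=float)
    if np.any(h < 0) or np.any(h > params.he_max + 1e-12):
        raise ValueError(f"he must lie in [0, {params.he_max}] μm")
    frac_lost = 1.0 - h / params.he_max
    pcl = params.pcl_hydrated_height - params.pcl_span * frac_lost
    mucus_change = -params.mucus_span * frac_lost
    if np.isscalar(he):
        return {"pcl_height": float(pcl), "mucus_height_change": float(mucus_change)}
    return {"pcl_height": pcl, "mucus_height_change": mucus_change}


@dataclass(frozen=True)
class ASLUpdate:
    """One ledger step: new heights plus the flux components that moved water.

    All fluxes in kg/(m²·s), positive magnitudes except ``delivered_flux``
    which is negative during condensation (water entering the ASL from air).
    The audit identity holds elementwise:

        delivered_flux + stored_rate − supply_flux
            + reabsorption_flux + overflow_flux = 0

    where stored_rate = Δhe·ρ_w/dt.
    """

    he: np.ndarray
    delivered_flux: np.ndarray      # water actually exchanged with the air
    supply_flux: np.ndarray         # mucosal supply used
    reabsorption_flux: np.ndarray   # excess removed through the epithelium
    overflow_flux: np.ndarray       # clamp loss past the reabsorption cap
    dry_capped: np.ndarray          # evaporation demand hit the supply cap
    overflowed: np.ndarray          # over-hydration clamp engaged


def update_asl(he, evaporation_flux, dt: float, params: ASLParameters) -> ASLUpdate:
    """Advance the hydration ledger one step of length ``dt``.

    ``evaporation_flux`` is the water flux demanded by the air side,
    kg/(m²·s), positive when water leaves the ASL (evaporation), negative for
    condensation. Supply is demand-led: it covers evaporation plus any
    deficit below he_max, up to the supply cap. A dry surface (he = 0) caps
    the flux actually delivered to air at the supply cap. Influx above he_max
    is removed by reabsorption up to its cap; any remainder is clamped and
    logged as over-hydration overflow.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    he0 = np.atleast_1d(np.asarray(he, dtype=float))
    e = np.broadcast_to(
        np.asarray(evaporation_flux, dtype=float), he0.shape
    ).astype(float)

    to_flux = _UM_TO_M * WATER_DENSITY / dt  # μm of water → kg/(m²·s)
    deficit_flux = (params.he_max - he0) * to_flux
    demand = np.maximum(e, 0.0) + deficit_flux
    supply = np.minimum(demand, params.supply_max_si)
    supply = np.where((he0 >= params.he_max) & (e <= 0.0), 0.0, supply)

    available = he0 * to_flux + supply
    delivered = np.where(e > 0.0, np.minimum(e, available), e)
    dry_capped = (e > 0.0) & (delivered < e)

    he_cand = he0 + (supply - delivered) / to_flux
    excess_flux = np.maximum(he_cand - params.he_max, 0.0) * to_flux
    reabsorbed = np.minimum(excess_flux, params.reabsorption_max_si)
    overflow = excess_flux - reabsorbed
    he_new = np.clip(he_cand - (reabsorbed + overflow) / to_flux, 0.0, params.he_max)

    return ASLUpdate(
        he=he_new,
        delivered_flux=delivered,
        supply_flux=supply,
        reabsorption_flux=reabsorbed,
        overflow_flux=overflow,
        dry_capped=dry_capped,
        overflowed=overflow > 0.0,
    )


@dataclass(frozen=True)
class DehydrationMetrics:
    min_he: np.ndarray                          # per segment, μm
    severely_dehydrated_anterior_fraction: float
    time_at_zero: np.ndarray                    # per segment, s


def dehydration_metrics(
    he_history: np.ndarray,
    positions: np.ndarray,
    times: np.ndarray | None = None,
    inhalation_mask: np.ndarray | None = None,
    atol: float = 1e-9,
) -> DehydrationMetrics:
    """Severity metrics over a simulated he history.

    Parameters
    ----------
    he_history : (n_times, n_segments) array, μm
    positions : per-segment X/L. Pass the posterior-edge X/L of each slab so
        the anterior fraction reads as the extent covered (1.0 when every
        segment dehydrates).
    times : per-row times, s; needed for ``time_at_zero`` (else zeros).
    inhalation_mask : boolean per row restricting the "reached zero" test to
        the inhalation phase; defaults to all rows.

    The anterior fraction is the largest X/L such that every segment at or
    before it reached he = 0 at some (masked) time.
    """
    hist = np.asarray(he_history, dtype=float)
    if hist.ndim != 2 or hist.size == 0:
        raise ValueError("he_history must be a non-empty (n_times, n_segments) array")
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] != hist.shape[1]:
        raise ValueError("positions length must match the segment axis")

    mask = np.ones(hist.shape[0], dtype=bool) if inhalation_mask is None else (
        np.asarray(inhalation_mask, dtype=bool)
    )
    masked = hist[mask] if mask.any() else hist[:0]

    min_he = hist.min(axis=0)
    hit_zero = (
        (masked <= atol).any(axis=0) if masked.size else np.zeros(hist.shape[1], bool)
    )
    order = np.argsort(pos)
    prefix = 0
    for idx in order:
        if hit_zero[idx]:
            prefix += 1
        else:
            break
    fraction = float(pos[order[prefix - 1]]) if prefix else 0.0

    if times is not None:
        t = np.asarray(times, dtype=float)
        dt = np.gradient(t) if t.size > 1 else np.zeros_like(t)
        at_zero = hist <= atol
        time_at_zero = (at_zero * dt[:, None]).sum(axis=0)
    else:
        time_at_zero = np.zeros(hist.shape[1])

    return DehydrationMetrics(
        min_he=min_he,
        severely_dehydrated_anterior_fraction=fraction,
        time_at_zero=time_at_zero,
    )
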