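"""Segmented two-passage nasal geometry.

Each passage is a series of geometric lumps (slabs of fixed thickness) with
per-slice cross-sectional area and perimeter; narrow-gap cross-sections are
characterised by their hydraulic diameter. Profiles can be read from CSV or
synthesised with a per-side congestion parameter that narrows the airway gap
(area scales, perimeter held).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AirwaySegment",
    "NasalGeometry",
    "SlitShapeParams",
    "hydraulic_diameter",
    "load_geometry",
    "write_geometry",
    "synthesize_geometry",
    "normalized_positions",
]

GEOMETRY_CSV_COLUMNS = ["side", "k", "x_m", "length_m", "area_m2", "perimeter_m"]

# tolerance on the isoperimetric inequality P^2 >= 4*pi*A, relative
_ISOPERIMETRIC_RTOL = 1e-9


def hydraulic_diameter(area: float, perimeter: float) -> float:
    """Hydraulic diameter Dh = 4·A/P of a duct cross-section.

    For a circle of radius r this gives 2r; for wide parallel plates of gap b
    it tends to 2b, matching the narrow-gap cross-sections modelled here.
    """
    a = np.asarray(area, dtype=float)
    p = np.asarray(perimeter, dtype=float)
    if np.any(a <= 0) or np.any(p <= 0):
        raise ValueError("area and perimeter must be positive")
    out = 4.0 * a / p
    return float(out) if np.isscalar(area) else out


@dataclass(frozen=True)
class AirwaySegment:
    """One geometric lump of a nasal passage.

    ``x`` is the axial position of the slab midpoint, measured from the
    anterior nasal valve, positive toward the choanae.
    """

    index: int
    x: float          # m, slab midpoint from anterior nasal valve
    length: float     # m, slice thickness
    area: float       # m²
    perimeter: float  # m

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"segment {self.index}: length must be positive")
        if self.area <= 0:
            raise ValueError(f"segment {self.index}: area must be positive")
        if self.perimeter <= 0:
            raise ValueError(f"segment {self.index}: perimeter must be positive")
        iso = self.perimeter**2 - 4.0 * math.pi * self.area
        if iso < -_ISOPERIMETRIC_RTOL * self.perimeter**2:
            raise ValueError(
                f"segment {self.index}: perimeter {self.perimeter} too small "
                f"for area {self.area} (violates P² ≥ 4πA)"
            )

    @property
    def hydraulic_diameter(self) -> float:
        return hydraulic_diameter(self.area, self.perimeter)


@dataclass(frozen=True)
class NasalGeometry:
    """Paired left/right series of airway segments, anterior → posterior."""

    left: tuple[AirwaySegment, ...]
    right: tuple[AirwaySegment, ...]
    slice_thickness: float

    def __post_init__(self) -> None:
        for name, side in (("left", self.left), ("right", self.right)):
            if len(side) < 1:
                raise ValueError(f"{name} passage has no segments")
            x = np.array([s.x for s in side])
            if np.any(np.diff(x) <= 0):
                raise ValueError(f"{name} passage not ordered anterior→posterior")
            lengths = np.array([s.length for s in side])
            edges_lo = x - lengths / 2
            edges_hi = x + lengths / 2
            if not np.allclose(edges_lo[1:], edges_hi[:-1], rtol=0, atol=1e-9):
                raise ValueError(f"{name} passage segments are not contiguous")

    def side(self, name: str) -> tuple[AirwaySegment, ...]:
        if name not in ("left", "right"):
            raise ValueError(f"unknown side {name!r}")
        return getattr(self, name)

    def areas(self, side: str) -> np.ndarray:
        return np.array([s.area for s in self.side(side)])

    def perimeters(self, side: str) -> np.ndarray:
        return np.array([s.perimeter for s in self.side(side)])

    def lengths(self, side: str) -> np.ndarray:
        return np.array([s.length for s in self.side(side)])

    def positions(self, side: str) -> np.ndarray:
        """Slab-midpoint axial positions, m."""
        return np.array([s.x for s in self.side(side)])

    def passage_length(self, side: str) -> float:
        return float(self.lengths(side).sum())

    def surface_area(self, side: str) -> float:
        """One-airway mucosal surface area Σ P(k)·l, m²."""
        return float((self.perimeters(side) * self.lengths(side)).sum())

    def effective_gaps(self, side: str) -> np.ndarray:
        """Diagnostic wall-to-wall gap Dh/2 of the narrow-gap section, m."""
        return hydraulic_diameter(self.areas(side), self.perimeters(side)) / 2.0


def normalized_positions(geometry: NasalGeometry) -> dict[str, np.ndarray]:
    """Per-segment non-dimensional position X/L of the slab midpoints.

    X/L = 0 at the anterior nasal valve and 1 at the posterior choanae; the
    first midpoint is ≈0 and the last ≈1 for thin slices.
    """
    out = {}
    for side in ("left", "right"):
        x = geometry.positions(side)
        out[side] = x / geometry.passage_length(side)
    return out


def edge_positions(geometry: NasalGeometry) -> dict[str, np.ndarray]:
    """Posterior-edge X/L of each slab (last edge is exactly 1)."""
    out = {}
    for side in ("left", "right"):
        x = geometry.positions(side) + geometry.lengths(side) / 2
        out[side] = x / geometry.passage_length(side)
    return out


# ---------------------------------------------------------------------------
# CSV I/O


def write_geometry(geometry: NasalGeometry, path: str | Path) -> None:
    """Write a geometry CSV (columns: side,k,x_m,length_m,area_m2,perimeter_m)."""
    rows = []
    for side in ("left", "right"):
        for seg in geometry.side(side):
            rows.append(
                {
                    "side": side,
                    "k": seg.index,
                    "x_m": seg.x,
                    "length_m": seg.length,
                    "area_m2": seg.area,
                    "perimeter_m": seg.perimeter,
                }
            )
    pd.DataFrame(rows, columns=GEOMETRY_CSV_COLUMNS).to_csv(path, index=False)


def load_geometry(path: str | Path, resample: bool = True) -> NasalGeometry:
    """Read a geometry CSV and return a validated :class:`NasalGeometry`.

    If the two sides differ in slice count or extent and ``resample`` is true,
    both are linearly resampled onto a common X/L grid (the finer of the two).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # parse failure surfaces the pandas message
        raise ValueError(f"{path}: cannot parse geometry CSV: {exc}") from exc
    missing = [c for c in GEOMETRY_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    sides: dict[str, list[AirwaySegment]] = {}
    for side in ("left", "right"):
        sub = df[df["side"] == side]
        if sub.empty:
            raise ValueError(f"{path}: no rows for side {side!r}")
        segs = []
        for row in sub.itertuples():
            line_no = row.Index + 2  # header is line 1
            try:
                segs.append(
                    AirwaySegment(
                        index=int(row.k),
                        x=float(row.x_m),
                        length=float(row.length_m),
                        area=float(row.area_m2),
                        perimeter=float(row.perimeter_m),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}: line {line_no}: {exc}") from exc
        sides[side] = segs

    thickness = sides["left"][0].length
    if resample and len(sides["left"]) != len(sides["right"]):
        return _resample_common_grid(sides["left"], sides["right"])
    return NasalGeometry(
        left=tuple(sides["left"]), right=tuple(sides["right"]), slice_thickness=thickness
    )


def _resample_common_grid(
    left: Sequence[AirwaySegment], right: Sequence[AirwaySegment]
) -> NasalGeometry:
    """Linearly resample A and P of both sides onto a common X/L grid."""
    n = max(len(left), len(right))
    length = max(sum(s.length for s in left), sum(s.length for s in right))
    dl = length / n
    x_new = (np.arange(n) + 0.5) * dl

    def resampled(side: Sequence[AirwaySegment]) -> tuple[AirwaySegment, ...]:
        total = sum(s.length for s in side)
        xl = np.array([s.x for s in side]) / total  # X/L of midpoints
        a = np.array([s.area for s in side])
        p = np.array([s.perimeter for s in side])
        xl_new = x_new / length
        a_new = np.interp(xl_new, xl, a)
        p_new = np.interp(xl_new, xl, p)
        return tuple(
            AirwaySegment(index=k, x=float(x_new[k]), length=dl,
                          area=float(a_new[k]), perimeter=float(p_new[k]))
            for k in range(n)
        )

    return NasalGeometry(left=resampled(left), right=resampled(right), slice_thickness=dl)


# ---------------------------------------------------------------------------
# Synthetic geometry


@dataclass(frozen=True)
class SlitShapeParams:
    """Shape parameters of the synthetic narrow-gap (slit) passage.

    The cross-section at each slice is a slit of gap ``b`` and developed wall
    width ``w``: A = b·w, P = 2(b+w). The gap runs from ``gap_end_m`` at the
    nasal valve and choanae to ``gap_mid_m`` mid-passage (half-sine bulge);
    the width follows a half-sine bulge of relative amplitude ``width_bulge``
    scaled so the one-side mucosal surface area Σ P·l hits
    ``surface_area_m2``.
    """

    gap_end_m: float = 1.4e-3
    gap_mid_m: float = 2.6e-3
    width_bulge: float = 0.3
    surface_area_m2: float = 0.01  # 100 cm² per passage

    def __post_init__(self) -> None:
        if not (0 < self.gap_end_m <= self.gap_mid_m):
            raise ValueError("need 0 < gap_end_m <= gap_mid_m")
        if not 0 <= self.width_bulge < 1:
            raise ValueError("width_bulge must be in [0, 1)")
        if self.surface_area_m2 <= 0:
            raise ValueError("surface_area_m2 must be positive")


def synthesize_geometry(
    n_slices: int = 120,
    slice_thickness: float = 0.78e-3,
    passage_length: float | None = None,
    shape_params: SlitShapeParams | None = None,
    congestion_left: float = 0.0,
    congestion_right: float = 0.0,
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> NasalGeometry:
    """Generate a smooth two-passage stand-in geometry.

    Per-side congestion ``c`` scales every area as A ← A·(1−c) with the
    perimeter held fixed (mucosal engorgement narrows the gap without
    shortening the walls). ``jitter`` adds a smooth multiplicative
    perturbation of the given relative amplitude to the gap profile
    (requires ``rng``).
    """
    if n_slices < 2:
        raise ValueError("n_slices must be >= 2")
    for name, c in (("congestion_left", congestion_left), ("congestion_right", congestion_right)):
        if not 0.0 <= c < 1.0:
            raise ValueError(f"{name} must be in [0, 1)")
    shape = shape_params or SlitShapeParams()
    if passage_length is not None:
        slice_thickness = passage_length / n_slices
    if slice_thickness <= 0:
        raise ValueError("slice_thickness must be positive")

    length = n_slices * slice_thickness
    x = (np.arange(n_slices) + 0.5) * slice_thickness
    xl = x / length

    gap = shape.gap_end_m + (shape.gap_mid_m - shape.gap_end_m) * np.sin(np.pi * xl)
    if jitter:
        if rng is None:
            raise ValueError("jitter requires an rng")
        gap = gap * (1.0 + jitter * _smooth_noise(xl, rng))
        if np.any(gap <= 0):
            raise ValueError("jitter produced a non-physical (non-positive) gap")

    width_shape = 1.0 + shape.width_bulge * np.sin(np.pi * xl)
    # solve the width scale so that sum 2*(gap+width)*l == surface_area
    w0 = (shape.surface_area_m2 / (2.0 * slice_thickness) - gap.sum()) / width_shape.sum()
    if w0 <= 0:
        raise ValueError(
            "surface_area_m2 too small for the requested gap profile and length"
        )
    width = w0 * width_shape

    area = gap * width
    perim = 2.0 * (gap + width)

    def build(congestion: float) -> tuple[AirwaySegment, ...]:
        a = area * (1.0 - congestion)
        return tuple(
            AirwaySegment(index=k, x=float(x[k]), length=slice_thickness,
                          area=float(a[k]), perimeter=float(perim[k]))
            for k in range(n_slices)
        )

    return NasalGeometry(
        left=build(congestion_left),
        right=build(congestion_right),
        slice_thickness=slice_thickness,
    )


def _smooth_noise(xl: np.ndarray, rng: np.random.Generator, modes: int = 4) -> np.ndarray:
    """Band-limited random profile in [-1, 1] built from a few Fourier modes."""
    out = np.zeros_like(xl)
    for m in range(1, modes + 1):
        out += rng.normal() / m * np.sin(np.pi * m * xl + rng.uniform(0, 2 * np.pi))
    peak = np.abs(out).max()
    return out / peak if peak > 0 else out
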