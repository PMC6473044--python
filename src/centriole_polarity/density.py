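"""Hexagon-normalized centriole density maps.

Each cell is modelled as a regular hexagon of equal area; the centriole's
centroid-relative offset is rescaled by ``sqrt(A_hex / area_cell)`` so all
cells share the reference hexagon's scale while offset *directions* are
preserved exactly.  Pooled normalized positions are binned on a raster over
the hexagon, optionally Gaussian-smoothed, and normalized so each pixel is
the probability of finding a centriole there in that set of cells.

The reference hexagon has one vertex on the +x (distal) axis: in a
polarized wild-type field density accumulates at that vertex, where the
wing hair forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geometry import CellGeometry, CentrioleRecord

__all__ = [
    "HexReferenceFrame",
    "DensityMap",
    "DensityComparison",
    "normalize_offset",
    "build_density_map",
    "compare_density_maps",
]


@dataclass(frozen=True)
class HexReferenceFrame:
    """Regular reference hexagon (vertex on +x) and its output raster.

    ``circumradius`` sets the dimensionless reference scale; the raster
    covers the square bounding box ``[-R, R] x [-R, R]`` with pixel centres,
    rows mapping to v (same sense as image rows) and columns to u.
    """

    circumradius: float = 1.0
    raster_shape: tuple[int, int] = (101, 101)

    @property
    def apothem(self) -> float:
        return self.circumradius * math.sqrt(3.0) / 2.0

    @property
    def area(self) -> float:
        return 3.0 * math.sqrt(3.0) / 2.0 * self.circumradius**2

    def vertices(self) -> np.ndarray:
        ang = np.deg2rad(np.arange(0, 360, 60))
        return self.circumradius * np.column_stack([np.cos(ang), np.sin(ang)])

    def boundary_radius(self, theta: np.ndarray | float) -> np.ndarray | float:
        """Distance from centre to the hexagon boundary along angle ``theta``."""
        d = np.mod(theta, math.pi / 3.0) - math.pi / 6.0
        return self.apothem / np.cos(d)

    def contains(self, u, v, tol: float = 1e-9):
        r = np.hypot(u, v)
        theta = np.arctan2(v, u)
        return r <= np.asarray(self.boundary_radius(theta)) * (1.0 + tol)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(u, v) coordinates of raster pixel centres, each of shape raster_shape."""
        nrows, ncols = self.raster_shape
        R = self.circumradius
        u = -R + (np.arange(ncols) + 0.5) * (2.0 * R / ncols)
        v = -R + (np.arange(nrows) + 0.5) * (2.0 * R / nrows)
        return np.meshgrid(u, v)

    def footprint(self) -> np.ndarray:
        """Boolean raster of pixels whose centre lies inside the hexagon."""
        uu, vv = self.pixel_centers()
        return self.contains(uu, vv)


@dataclass
class DensityMap:
    """Probability raster of centriole positions over the reference hexagon."""

    grid: np.ndarray = field(repr=False)
    n_centrioles: int = 0
    group: str | None = None
    frame: HexReferenceFrame = field(default_factory=HexReferenceFrame)

    def center_of_mass(self) -> tuple[float, float]:
        """Probability-weighted mean (u, v) position."""
        uu, vv = self.frame.pixel_centers()
        return float((self.grid * uu).sum()), float((self.grid * vv).sum())


@dataclass
class DensityComparison:
    displacement: tuple[float, float]
    tv_distance: float


def normalize_offset(
    record: CentrioleRecord,
    cell: CellGeometry,
    frame: HexReferenceFrame | None = None,
) -> tuple[float, float]:
    """Map a centroid-relative offset into reference-hexagon coordinates.

    The offset is scaled by ``sqrt(A_hex / area_px)`` (equal-area
    normalization), preserving its direction exactly; points falling outside
    the reference hexagon -- real cells are not perfect hexagons -- are
    clamped radially to the boundary so no centriole is discarded.
    """
    if frame is None:
        frame = HexReferenceFrame()
    if cell.area_px <= 0:
        raise ValueError(f"cell {cell.label} has zero area")
    scale = math.sqrt(frame.area / cell.area_px)
    u = record.offset[0] * scale
    v = record.offset[1] * scale
    r = math.hypot(u, v)
    if r > 0.0:
        rb = float(frame.boundary_radius(math.atan2(v, u)))
        if r > rb:
            u *= rb / r
            v *= rb / r
    return (u, v)


def build_density_map(
    records: Sequence[CentrioleRecord],
    cells: Sequence[CellGeometry],
    frame: HexReferenceFrame | None = None,
    smoothing_sigma: float = 2.0,
    group: str | None = None,
) -> DensityMap:
    """Histogram of hexagon-normalized centriole positions, as probabilities.

    ``smoothing_sigma`` (raster pixels) applies an optional Gaussian blur;
    pixels outside the hexagon footprint are zeroed and the grid is
    re-normalized to sum to 1 afterwards.  ``smoothing_sigma=0`` gives the
    raw histogram.
    """
    if frame is None:
        frame = HexReferenceFrame()
    by_label = {c.label: c for c in cells}
    pts = []
    for rec in records:
        cell = by_label.get(rec.cell_label)
        if cell is None:
            continue
        pts.append(normalize_offset(rec, cell, frame))
    if not pts:
        raise ValueError("no centriole records to map")
    uv = np.asarray(pts)
    R = frame.circumradius
    nrows, ncols = frame.raster_shape
    eps = 1e-9 * R  # boundary-clamped points belong to the edge bins
    u = np.clip(uv[:, 0], -R, R - eps)
    v = np.clip(uv[:, 1], -R, R - eps)
    grid, _, _ = np.histogram2d(
        v, u, bins=frame.raster_shape, range=[[-R, R], [-R, R]]
    )
    if smoothing_sigma and smoothing_sigma > 0:
        grid = ndimage.gaussian_filter(grid, sigma=smoothing_sigma)
    grid[~frame.footprint()] = 0.0
    total = grid.sum()
    if total <= 0:
        raise ValueError("density map has no in-hexagon mass")
    grid = grid / total
    return DensityMap(grid=grid, n_centrioles=len(pts), group=group, frame=frame)


def compare_density_maps(map_a: DensityMap, map_b: DensityMap) -> DensityComparison:
    """Descriptive divergence between two density maps.

    Returns the displacement of B's centre of mass relative to A's and the
    total-variation distance ``0.5 * sum(|a - b|)`` between the probability
    grids.
    """
    if map_a.grid.shape != map_b.grid.shape:
        raise ValueError(
            f"raster shape mismatch: {map_a.grid.shape} vs {map_b.grid.shape}"
        )
    ca = map_a.center_of_mass()
    cb = map_b.center_of_mass()
    tv = 0.5 * float(np.abs(map_a.grid - map_b.grid).sum())
    return DensityComparison(
        displacement=(cb[0] - ca[0], cb[1] - ca[1]), tv_distance=tv
    )
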