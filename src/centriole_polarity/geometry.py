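"""Cell geometry extraction from label masks and centriole-to-cell assignment.

Tissue coordinate convention used throughout the package: ``x`` is the image
column (increasing rightward, which by acquisition convention is the distal
direction of the wing) and ``y`` is the image row.  All positions are
0-based pixel-centre coordinates.

A *label mask* is an integer raster in which all pixels of one cell share a
unique positive label and background (the membrane skeleton between cells)
is 0 -- the standard output of junction-segmentation tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skimage import measure

__all__ = [
    "LabelMask",
    "CellGeometry",
    "CentrioleRecord",
    "extract_cell_geometries",
    "assign_centrioles",
    "label_at",
]


@dataclass(frozen=True)
class LabelMask:
    """Integer-labelled segmentation raster.

    Parameters
    ----------
    pixels
        2-D integer array indexed ``(row, column)``.  Cell labels are >= 1,
        background is 0.
    pixel_size
        Physical units per pixel.  Only carried as metadata; all geometry in
        this package is computed in pixel units.
    """

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("invalid mask: expected a 2-D integer raster")
        if not (arr > 0).any():
            raise ValueError("no cells: mask contains no nonzero labels")
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class CellGeometry:
    """Geometry of one segmented cell in tissue coordinates.

    ``centroid`` is the unweighted mean of the cell's pixel coordinates;
    ``axial_min``/``axial_max`` are the minimal and maximal pixel
    x-coordinates of the cell (the extents along the polarity axis);
    ``boundary`` is an ordered (N, 2) array of ``(x, y)`` outline vertices.
    """

    label: int
    centroid: tuple[float, float]
    area_px: int
    axial_min: float
    axial_max: float
    boundary: np.ndarray = field(repr=False)
    touches_border: bool = False
    group: str | None = None


@dataclass
class CentrioleRecord:
    """One centriole detection assigned to its owning cell.

    ``offset`` is ``position - centroid`` of the owning cell, the quantity
    every downstream polarity statistic is built on.
    """

    position: tuple[float, float]
    cell_label: int
    offset: tuple[float, float]
    group: str | None = None


def _as_label_array(mask: LabelMask | np.ndarray) -> np.ndarray:
    if isinstance(mask, LabelMask):
        return mask.pixels
    return LabelMask(np.asarray(mask)).pixels


def _region_boundary(region, shape: tuple[int, int]) -> np.ndarray:
    """Ordered outline of one region as (x, y) vertices in image coordinates."""
    padded = np.pad(region.image, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len)
    minr, minc = region.bbox[0], region.bbox[1]
    rows = contour[:, 0] + (minr - 1)
    cols = contour[:, 1] + (minc - 1)
    return np.column_stack([cols, rows])


def extract_cell_geometries(
    mask: LabelMask | np.ndarray,
    min_area: int = 20,
) -> list[CellGeometry]:
    """Measure every labelled cell of a segmentation mask.

    Cells with fewer than ``min_area`` pixels are dropped (segmentation
    slivers); cells whose bounding box touches the image border are kept but
    flagged ``touches_border=True`` because their axial extents are
    truncated, which would bias polarity scores.

    Returns one :class:`CellGeometry` per retained label, sorted by label.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    arr = _as_label_array(mask)
    nrows, ncols = arr.shape
    out: list[CellGeometry] = []
    for region in measure.regionprops(arr):
        if region.area < min_area:
            continue
        row_c, col_c = region.centroid
        minr, minc, maxr, maxc = region.bbox
        touches = minr == 0 or minc == 0 or maxr == nrows or maxc == ncols
        out.append(
            CellGeometry(
                label=int(region.label),
                centroid=(float(col_c), float(row_c)),
                area_px=int(region.area),
                axial_min=float(minc),
                axial_max=float(maxc - 1),
                boundary=_region_boundary(region, arr.shape),
                touches_border=bool(touches),
            )
        )
    return out


def label_at(mask: LabelMask | np.ndarray, x: float, y: float) -> int:
    """Label of the pixel containing tissue coordinate ``(x, y)`` (0 = background)."""
    arr = _as_label_array(mask)
    i, j = int(round(y)), int(round(x))
    if not (0 <= i < arr.shape[0] and 0 <= j < arr.shape[1]):
        raise ValueError(f"detection ({x}, {y}) outside image bounds {arr.shape}")
    return int(arr[i, j])


def _snap_offsets(radius: float) -> np.ndarray:
    """Integer pixel offsets within ``radius``, ordered by distance."""
    r = int(np.ceil(radius))
    di, dj = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = di**2 + dj**2
    keep = d2 <= radius**2
    order = np.argsort(d2[keep], kind="stable")
    return np.column_stack([di[keep], dj[keep]])[order]


def assign_centrioles(
    mask: LabelMask | np.ndarray,
    cells: Sequence[CellGeometry],
    detections: Sequence[tuple[float, float]],
    group_map: Mapping[int, str] | None = None,
    snap_radius: float = 2.0,
) -> tuple[list[CentrioleRecord], list[tuple[float, float]]]:
    """Assign each detection to the cell whose pixel set contains it.

    Detections landing on a background pixel (the 1-2 px membrane skeleton)
    are snapped to the nearest labelled pixel within ``snap_radius`` pixels;
    detections that cannot be resolved, or whose label was filtered out of
    ``cells``, are returned in the second element rather than silently
    dropped.

    Raises ``ValueError`` for detections outside the image bounds.
    """
    if len(detections) == 0:
        raise ValueError("detections must be nonempty")
    arr = _as_label_array(mask)
    by_label = {c.label: c for c in cells}
    offsets = _snap_offsets(snap_radius)

    assigned: list[CentrioleRecord] = []
    unassigned: list[tuple[float, float]] = []
    for x, y in detections:
        x, y = float(x), float(y)
        i, j = int(round(y)), int(round(x))
        if not (0 <= i < arr.shape[0] and 0 <= j < arr.shape[1]):
            raise ValueError(
                f"detection ({x}, {y}) outside image bounds {arr.shape}"
            )
        lab = int(arr[i, j])
        if lab == 0:
            for di, dj in offsets:
                ii, jj = i + di, j + dj
                if 0 <= ii < arr.shape[0] and 0 <= jj < arr.shape[1] and arr[ii, jj]:
                    lab = int(arr[ii, jj])
                    break
        cell = by_label.get(lab)
        if lab == 0 or cell is None:
            unassigned.append((x, y))
            continue
        cx, cy = cell.centroid
        group = group_map.get(lab) if group_map is not None else cell.group
        assigned.append(
            CentrioleRecord(
                position=(x, y),
                cell_label=lab,
                offset=(x - cx, y - cy),
                group=group,
            )
        )
    return assigned, unassigned
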