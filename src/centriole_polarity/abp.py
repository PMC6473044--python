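"""Average Basal Body Position (ABP) scoring.

Each centriole's position along the polarity axis is normalized piecewise
to the owning cell's axial extents: -1.0 at the cell's minimal x
coordinate, 0 at the centroid, +1.0 at the maximal x coordinate.  The
per-image ABP score is the mean over all scored centrioles in the image.
A positive image score means the centriole population sits distally
(toward +x) of the cell centroids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import CellGeometry, CentrioleRecord

__all__ = ["AbpResult", "abp_score", "abp_image"]


@dataclass
class AbpResult:
    """Per-centriole ABP scores and their per-image mean."""

    per_centriole: list[tuple[int, float]]
    image_score: float
    n: int


def abp_score(record: CentrioleRecord, cell: CellGeometry) -> float:
    """Normalized axial position of one centriole in its cell.

    With ``dx = x_centriole - x_centroid`` the score is
    ``dx / (axial_max - x_centroid)`` for ``dx >= 0`` and
    ``dx / (x_centroid - axial_min)`` otherwise, clamped to [-1, 1] to
    absorb raster edge effects when a detection snaps just outside the
    pixel extent range.
    """
    cx = cell.centroid[0]
    if cell.axial_max <= cx or cx <= cell.axial_min:
        raise ValueError(f"degenerate cell {cell.label}: zero axial extent")
    dx = record.position[0] - cx
    denom = (cell.axial_max - cx) if dx >= 0 else (cx - cell.axial_min)
    return float(np.clip(dx / denom, -1.0, 1.0))


def abp_image(
    records: Sequence[CentrioleRecord],
    cells: Sequence[CellGeometry],
    include_border: bool = False,
    per_cell_mean: bool = False,
) -> AbpResult:
    """ABP score of one image.

    Centrioles in border-touching cells are excluded unless
    ``include_border`` is set, because truncated axial extents bias the
    normalization.  By default every centriole enters the image mean
    individually (wing cells carry two, often nearly coincident);
    ``per_cell_mean=True`` averages within each cell first, for sensitivity
    analysis of that choice.
    """
    by_label = {c.label: c for c in cells}
    scores: list[tuple[int, float]] = []
    for rec in records:
        cell = by_label.get(rec.cell_label)
        if cell is None:
            continue
        if cell.touches_border and not include_border:
            continue
        scores.append((rec.cell_label, abp_score(rec, cell)))
    if not scores:
        raise ValueError("no scorable centriole records")
    if per_cell_mean:
        per_cell: dict[int, list[float]] = {}
        for lab, s in scores:
            per_cell.setdefault(lab, []).append(s)
        image_score = float(np.mean([np.mean(v) for v in per_cell.values()]))
    else:
        image_score = float(np.mean([s for _, s in scores]))
    return AbpResult(per_centriole=scores, image_score=image_score, n=len(scores))
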