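"""Q-method: angular quartile classification of centriole offsets.

The direction of each centriole's centroid-relative offset is measured
from the +x (distal) axis and binned into four 90-degree sectors:

* Q1: angle in [-pi/4,  pi/4)   -- centred on the distal direction
* Q2: angle in [ pi/4, 3pi/4)
* Q3: angle in [-3pi/4, -pi/4)
* Q4: the remainder ([3pi/4, pi] and (-pi, -3pi/4))

Boundaries are half-open on the counterclockwise-lower end so that every
defined angle lands in exactly one sector.  A polarized wild-type field
concentrates centrioles in Q1; an unpolarized field spreads them ~25% per
sector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .geometry import CentrioleRecord

__all__ = [
    "QUARTILES",
    "QuartileDistribution",
    "centriole_angle",
    "assign_quartile",
    "quartile_distribution",
]

QUARTILES = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class QuartileDistribution:
    """Counts and fractions of centrioles per angular quartile for one group.

    ``n_excluded`` counts centrioles with undefined angle (offset exactly
    zero); they enter neither counts nor fractions.
    """

    group: str | None
    counts: tuple[int, int, int, int]
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    @property
    def fractions(self) -> tuple[float, float, float, float]:
        total = self.n
        if total == 0:
            return (math.nan,) * 4
        return tuple(c / total for c in self.counts)


def centriole_angle(record: CentrioleRecord) -> float:
    """Angle of the offset vector in (-pi, pi], measured from +x.

    Raises ``ValueError("undefined angle")`` for a zero offset (centriole
    exactly at the centroid), which callers tally as excluded.
    """
    dx, dy = record.offset
    if dx == 0.0 and dy == 0.0:
        raise ValueError("undefined angle: centriole at the cell centroid")
    angle = math.atan2(dy, dx)
    if angle == -math.pi:
        angle = math.pi
    return angle


def assign_quartile(angle: float) -> str:
    """Quartile label for an angle in radians (any finite value accepted)."""
    if not math.isfinite(angle):
        raise ValueError("angle must be finite")
    a = math.remainder(angle, 2.0 * math.pi)  # (-pi, pi] up to sign of pi
    if a == -math.pi:
        a = math.pi
    q = math.pi / 4.0
    if -q <= a < q:
        return "Q1"
    if q <= a < 3.0 * q:
        return "Q2"
    if -3.0 * q <= a < -q:
        return "Q3"
    return "Q4"


def quartile_distribution(
    records: Sequence[CentrioleRecord],
    group_key: Callable[[CentrioleRecord], str | None] | None = None,
) -> list[QuartileDistribution]:
    """Tabulate per-group quartile counts over a set of centriole records.

    ``group_key`` defaults to the record's ``group`` tag; records with zero
    offset are tallied in ``n_excluded`` for their group.  Groups are
    returned in first-appearance order.
    """
    if group_key is None:
        group_key = lambda r: r.group  # noqa: E731
    order: list[str | None] = []
    counts: dict[str | None, np.ndarray] = {}
    excluded: dict[str | None, int] = {}
    for rec in records:
        g = group_key(rec)
        if g not in counts:
            order.append(g)
            counts[g] = np.zeros(4, dtype=int)
            excluded[g] = 0
        try:
            angle = centriole_angle(rec)
        except ValueError:
            excluded[g] += 1
            continue
        counts[g][QUARTILES.index(assign_quartile(angle))] += 1
    return [
        QuartileDistribution(
            group=g, counts=tuple(int(c) for c in counts[g]), n_excluded=excluded[g]
        )
        for g in order
    ]
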