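"""Hotspot level extraction via the iterated Lorenz-derivative (Loubar) threshold.

The Lorenz curve of a set of cell outflows plots, with cells sorted in
ascending order of activity, the cumulative fraction of cells against the
cumulative fraction of total outflow. The Loubar threshold is found by taking
the tangent to the curve at (1, 1) — for the piecewise-linear empirical curve
this is the slope of the final segment, ``n * max / sum`` — and intersecting
it with the x-axis at ``x* = 1 - 1/s``. Cells whose sorted position exceeds
``x*`` are the hotspots of the current level. Selected cells are removed and
the construction is repeated on the reduced distribution, producing an ordered
hierarchy of levels 1 (most active) through L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateDistributionError

#: slope within this tolerance of 1 means the distribution is flat (the
#: Lorenz curve is the equality diagonal) and no threshold exists.
FLAT_SLOPE_TOL = 1e-9


@dataclass(frozen=True)
class LorenzCurve:
    """Piecewise-linear empirical Lorenz curve as an (n+1, 2) point array."""

    points: np.ndarray

    @property
    def final_slope(self) -> float:
        """Derivative at (1, 1): the slope of the last segment."""
        (x0, y0), (x1, y1) = self.points[-2], self.points[-1]
        return (y1 - y0) / (x1 - x0)


@dataclass(frozen=True)
class LoubarSplit:
    """Result of one tangent construction on an outflow distribution."""

    threshold: float
    hotspot_indices: tuple[int, ...]  # positions in the *input* list
    flat: bool
    slope: float
    x_intercept: float


@dataclass
class HotspotAssignment:
    """Partition of cells into ordered activity levels 1..L (1 = top)."""

    level: dict[str, int]
    thresholds: list[float]
    L: int
    meta: dict = field(default_factory=dict)

    def cells_at(self, lvl: int) -> list[str]:
        return [cid for cid, l in self.level.items() if l == lvl]


def lorenz_curve(values) -> LorenzCurve:
    """Empirical Lorenz curve of non-negative values (ascending sort).

    Point k is ``(k/n, sum of k smallest / total)``; the curve runs from
    (0, 0) to (1, 1) and is convex.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0 or v.sum() <= 0:
        raise DegenerateDistributionError(
            "Lorenz curve needs at least one strictly positive value"
        )
    if (v < 0).any():
        raise DegenerateDistributionError("outflows must be non-negative")
    n = v.size
    s = np.sort(v)
    x = np.arange(n + 1) / n
    y = np.concatenate([[0.0], np.cumsum(s)]) / s.sum()
    return LorenzCurve(np.column_stack([x, y]))


def loubar_split(values, tol: float = FLAT_SLOPE_TOL) -> LoubarSplit:
    """One Loubar tangent construction over a list of outflow values.

    Returns the selected hotspot positions (indices into ``values``), the
    reported threshold (smallest selected outflow) and the flat flag. When the
    final-segment slope is within ``tol`` of 1 the distribution is flat: all
    cells are returned as a single group with ``flat=True``.

    Ties at the cut are resolved deterministically: every cell whose outflow
    strictly exceeds the boundary value is selected, then remaining slots are
    filled from boundary-valued cells in stable input order.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0 or v.sum() <= 0:
        raise DegenerateDistributionError(
            "Loubar split needs at least one strictly positive value"
        )
    n = v.size
    slope = n * v.max() / v.sum()
    if slope <= 1 + tol:
        return LoubarSplit(float(v.min()), tuple(range(n)), True, float(slope), 0.0)
    x_star = 1.0 - 1.0 / slope
    # positions k/n > x*  =>  k > n*x*; the +1e-9 guards float noise when
    # n*x* is an exact integer
    n_hot = n - math.floor(n * x_star + 1e-9)
    n_hot = max(1, min(n, n_hot))

    order = np.argsort(v, kind="stable")
    boundary = float(v[order[n - n_hot]])
    strict = [i for i in range(n) if v[i] > boundary]
    at_boundary = [i for i in range(n) if v[i] == boundary]
    selected = strict + at_boundary[: n_hot - len(strict)]
    return LoubarSplit(boundary, tuple(sorted(selected)), False,
                       float(slope), float(x_star))


def assign_levels(outflows: dict[str, float], min_cells: int = 1) -> HotspotAssignment:
    """Iterate the Loubar construction to a full hierarchy of hotspot levels.

    Level-1 hotspots are extracted from the full outflow distribution; they
    are then removed and the threshold recomputed on the remainder, yielding
    level 2, and so on. Iteration stops when the flat flag fires, when fewer
    than ``min_cells`` cells remain, or when no positive-outflow cell remains;
    everything still unassigned (including zero-outflow cells) becomes the
    final level L.
    """
    ids = list(outflows)
    vals = {i: float(outflows[i]) for i in ids}
    if not ids or max(vals.values()) <= 0:
        raise DegenerateDistributionError("no positive outflow in the network")
    if any(v < 0 for v in vals.values()):
        raise DegenerateDistributionError("outflows must be non-negative")

    level: dict[str, int] = {}
    thresholds: list[float] = []
    remaining = ids
    lvl = 0
    flat_stop = False
    while remaining:
        values = [vals[i] for i in remaining]
        if len(remaining) < min_cells or max(values) <= 0:
            break
        split = loubar_split(values)
        if split.flat:
            flat_stop = True
            break
        lvl += 1
        chosen = {remaining[k] for k in split.hotspot_indices}
        for cid in chosen:
            level[cid] = lvl
        thresholds.append(split.threshold)
        remaining = [i for i in remaining if i not in chosen]

    if remaining:
        lvl += 1
        for cid in remaining:
            level[cid] = lvl
        thresholds.append(min(vals[i] for i in remaining))

    return HotspotAssignment(
        level=level,
        thresholds=thresholds,
        L=lvl,
        meta={
            "flat_stop": flat_stop,
            "min_cells": min_cells,
            "zero_outflow_policy": "assigned to final level L",
        },
    )
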