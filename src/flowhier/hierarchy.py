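"""The flow-hierarchy metric Φ, its level-flow matrix, and null models.

With cells partitioned into hotspot levels 1..L, the level-flow matrix T has
entries T_ij = (trips from level-i cells to level-j cells) / (total trips).
The flow-hierarchy is the tri-diagonal trace of T,

    Φ = Σ_{i=1}^{L-1} (T_ii + T_i,i+1 + T_i+1,i) + T_LL ,

which is 1 when all flow runs between same- or adjacent-level hotspots
(tree-like organisation) and approaches its uniform floor when flow is spread
evenly across level pairs. Two reference values accompany Φ:

* the uniform null Φ_u = (3L - 2)/L², the value of a uniform T; and
* the rewired null Φ_h, the Φ of the matrix rebuilt from T's row and column
  marginals as if origin and destination levels were paired independently
  (a configuration-style randomisation that keeps the flow distribution
  across levels but destroys level-to-level correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConsistencyError, FlowHierError
from .hotspots import HotspotAssignment, assign_levels
from .network_io import TripNetwork, outflows

#: relative tolerance on "entries sum to 1" when validating a matrix
NORMALIZATION_RTOL = 1e-8


@dataclass
class LevelFlowMatrix:
    """L×L matrix of (normalized) trips between hotspot levels."""

    T: np.ndarray
    L: int

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float)
        if self.T.shape != (self.L, self.L):
            raise FlowHierError(
                f"matrix shape {self.T.shape} does not match L={self.L}"
            )
        if (self.T < 0).any():
            raise FlowHierError("level-flow matrix has negative entries")

    @property
    def is_normalized(self) -> bool:
        return abs(self.T.sum() - 1.0) <= NORMALIZATION_RTOL

    def normalized(self) -> "LevelFlowMatrix":
        total = self.T.sum()
        if total <= 0:
            raise FlowHierError("cannot normalize an all-zero matrix")
        return LevelFlowMatrix(self.T / total, self.L)


@dataclass
class HierarchyResult:
    """Φ for one city together with its null references and level summaries."""

    phi: float
    L: int
    phi_uniform: float
    phi_rewired: float | None = None
    level_counts: list[int] = field(default_factory=list)
    level_outflow_shares: list[float] = field(default_factory=list)
    matrix: LevelFlowMatrix | None = None
    meta: dict = field(default_factory=dict)


def level_flow_matrix(network: TripNetwork,
                      assignment: HotspotAssignment) -> LevelFlowMatrix:
    """Bucket every inter-cell flow by its (origin level, destination level)
    and normalize by the total flow so entries sum to 1."""
    L = assignment.L
    T = np.zeros((L, L))
    lev = assignment.level
    for (o, d), w in network.flows.items():
        try:
            i, j = lev[o], lev[d]
        except KeyError as exc:
            raise ConsistencyError(
                f"flow endpoint {exc.args[0]!r} has no hotspot level"
            ) from None
        T[i - 1, j - 1] += w
    total = T.sum()
    if total <= 0:
        raise FlowHierError("network has zero total flow")
    return LevelFlowMatrix(T / total, L)


def _as_matrix(T) -> LevelFlowMatrix:
    if isinstance(T, LevelFlowMatrix):
        return T
    arr = np.asarray(T, dtype=float)
    return LevelFlowMatrix(arr, arr.shape[0])


def flow_hierarchy(T) -> float:
    """Tri-diagonal trace Φ of a normalized level-flow matrix.

    Accepts a :class:`LevelFlowMatrix` or a square array. Raises if the
    entries do not sum to 1 within tolerance. For L = 1 the band is the whole
    matrix and Φ = 1.
    """
    m = _as_matrix(T)
    if not m.is_normalized:
        raise FlowHierError(
            f"matrix entries sum to {m.T.sum():.6g}, expected 1; "
            "normalize before computing the hierarchy"
        )
    A = m.T
    phi = float(np.trace(A) + np.trace(A, offset=1) + np.trace(A, offset=-1))
    return min(phi, 1.0)  # clip float dust just above 1


def uniform_null_phi(L: int) -> float:
    """Closed-form Φ of a uniformly filled L×L matrix: (3L - 2) / L²."""
    if L < 1:
        raise FlowHierError(f"L must be a positive integer, got {L}")
    return (3 * L - 2) / (L * L)


def rewired_null(T) -> tuple[LevelFlowMatrix, float]:
    """Marginal-preserving rewired null matrix and its Φ.

    T_h[i, j] = (row sum i) × (column sum j) / (grand total). Row and column
    sums of T_h equal those of T exactly; the construction is valid on raw
    count matrices too (the grand total then differs from 1 and Φ is computed
    on the normalized copy).
    """
    m = _as_matrix(T)
    grand = m.T.sum()
    if grand <= 0:
        raise FlowHierError("cannot rewire an all-zero matrix")
    rows = m.T.sum(axis=1)
    cols = m.T.sum(axis=0)
    T_h = LevelFlowMatrix(np.outer(rows, cols) / grand, m.L)
    phi_h = flow_hierarchy(T_h.normalized())
    return T_h, phi_h


def city_phi(network: TripNetwork,
             min_cells: int = 1,
             include_rewired: bool = True) -> HierarchyResult:
    """End-to-end Φ for one city: outflows → hotspot levels → level-flow
    matrix → Φ with its uniform (and optionally rewired) null values."""
    network.validate()
    out = outflows(network)
    assignment = assign_levels(out, min_cells=min_cells)
    matrix = level_flow_matrix(network, assignment)
    phi = flow_hierarchy(matrix)

    total_out = sum(out.values())
    counts = [0] * assignment.L
    shares = [0.0] * assignment.L
    for cid, lvl in assignment.level.items():
        counts[lvl - 1] += 1
        shares[lvl - 1] += out[cid] / total_out

    phi_rw = None
    if include_rewired:
        _, phi_rw = rewired_null(matrix)

    return HierarchyResult(
        phi=phi,
        L=assignment.L,
        phi_uniform=uniform_null_phi(assignment.L),
        phi_rewired=phi_rw,
        level_counts=counts,
        level_outflow_shares=shares,
        matrix=matrix,
        meta={"min_cells": min_cells, **assignment.meta},
    )
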