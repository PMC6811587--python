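"""Reading, writing, validation and spatial coarse-graining of trip networks.

A trip network is a weighted directed graph whose nodes are spatial cells
(planar km coordinates, optional population) and whose edge weights are trip
counts. Intra-cell (diagonal) flows are excluded throughout: the analysis is
about movement *between* places. Geographic inputs must be pre-projected to a
planar km frame before they reach this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyNetworkError,
    FlowHierError,
    FormatError,
    ReferentialError,
)

EDGE_COLUMNS = ("origin", "destination", "weight")
CELL_COLUMNS = ("id", "x", "y")


@dataclass(frozen=True)
class Cell:
    """A spatial cell: opaque id, planar coordinates in km, optional population."""

    id: str
    x: float
    y: float
    population: float | None = None

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise FlowHierError(f"cell {self.id!r} has non-finite coordinates")
        if self.population is not None and self.population < 0:
            raise FlowHierError(f"cell {self.id!r} has negative population")


@dataclass
class TripNetwork:
    """Directed inter-cell trip flows over a set of cells.

    ``flows`` maps ordered ``(origin, destination)`` id pairs to non-negative
    trip weights; self-pairs are never stored. ``meta`` carries provenance
    (dropped self-loop counts, generator configs, ...).
    """

    cells: dict[str, Cell]
    flows: dict[tuple[str, str], float]
    meta: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def total_flow(self) -> float:
        return float(sum(self.flows.values()))

    def validate(self) -> "TripNetwork":
        """Check structural invariants; return self for chaining."""
        for (o, d), w in self.flows.items():
            if o == d:
                raise FlowHierError(f"self-flow stored for cell {o!r}")
            if w < 0:
                raise FlowHierError(f"negative flow weight on ({o!r}, {d!r})")
            if o not in self.cells or d not in self.cells:
                missing = [c for c in (o, d) if c not in self.cells]
                raise ReferentialError(
                    f"flow endpoints missing from cell table: {missing}"
                )
        if self.total_flow <= 0:
            raise EmptyNetworkError("network has zero total flow")
        return self


def read_network(edge_path: str | Path, cells_path: str | Path) -> TripNetwork:
    """Read a trip network from an edge-list CSV and a cell-table CSV.

    The edge file needs columns ``origin,destination,weight``; the cell file
    ``id,x,y`` with an optional ``population`` column. Self-loop rows are
    dropped (their count is recorded in ``meta['dropped_self_loops']``) and
    duplicate (origin, destination) rows are summed.
    """
    edges = pd.read_csv(edge_path, dtype={"origin": str, "destination": str},
                        float_precision="round_trip")
    for col in EDGE_COLUMNS:
        if col not in edges.columns:
            raise FormatError(f"edge file {edge_path} is missing column {col!r}")
    cells_df = pd.read_csv(cells_path, dtype={"id": str},
                           float_precision="round_trip")
    for col in CELL_COLUMNS:
        if col not in cells_df.columns:
            raise FormatError(f"cell file {cells_path} is missing column {col!r}")
    if cells_df["id"].duplicated().any():
        dupes = cells_df.loc[cells_df["id"].duplicated(), "id"].tolist()
        raise FormatError(f"duplicate cell ids in {cells_path}: {dupes}")

    weights = pd.to_numeric(edges["weight"], errors="coerce")
    if weights.isna().any() or (weights < 0).any():
        bad = edges.loc[weights.isna() | (weights < 0)].index.tolist()
        raise FormatError(f"non-numeric or negative weights at rows {bad[:10]}")
    edges = edges.assign(weight=weights)

    has_pop = "population" in cells_df.columns
    cells: dict[str, Cell] = {}
    for row in cells_df.itertuples(index=False):
        pop = getattr(row, "population", None) if has_pop else None
        if pop is not None and pd.isna(pop):
            pop = None
        cells[row.id] = Cell(row.id, float(row.x), float(row.y),
                             None if pop is None else float(pop))

    unknown = set(edges["origin"]).union(edges["destination"]) - set(cells)
    if unknown:
        raise ReferentialError(
            f"flow endpoints absent from cell table: {sorted(unknown)}"
        )

    self_mask = edges["origin"] == edges["destination"]
    dropped = int(self_mask.sum())
    edges = edges.loc[~self_mask]
    grouped = edges.groupby(["origin", "destination"], sort=False)["weight"].sum()

    flows = {(o, d): float(w) for (o, d), w in grouped.items() if w > 0}
    network = TripNetwork(cells, flows, meta={"dropped_self_loops": dropped})
    return network.validate()


def write_network(network: TripNetwork,
                  edge_path: str | Path,
                  cells_path: str | Path) -> None:
    """Write a network to the edge-list / cell-table CSV pair read by
    :func:`read_network`. Round-trips flows and coordinates at full precision."""
    network.validate()
    edge_rows = [
        {"origin": o, "destination": d, "weight": repr(float(w))}
        for (o, d), w in network.flows.items()
    ]
    pd.DataFrame(edge_rows, columns=list(EDGE_COLUMNS)).to_csv(edge_path, index=False)

    any_pop = any(c.population is not None for c in network.cells.values())
    cell_rows = []
    for c in network.cells.values():
        row = {"id": c.id, "x": repr(float(c.x)), "y": repr(float(c.y))}
        if any_pop:
            row["population"] = "" if c.population is None else repr(float(c.population))
        cell_rows.append(row)
    cols = list(CELL_COLUMNS) + (["population"] if any_pop else [])
    pd.DataFrame(cell_rows, columns=cols).to_csv(cells_path, index=False)


def outflows(network: TripNetwork) -> dict[str, float]:
    """Total outgoing trip weight per cell (zero for cells with no out-edges).

    The sum over all entries equals the total network flow.
    """
    out = {cid: 0.0 for cid in network.cells}
    for (o, _d), w in network.flows.items():
        out[o] += w
    return out


def coarse_grain(network: TripNetwork, cell_size: float) -> TripNetwork:
    """Re-aggregate a network onto a square grid of side ``cell_size`` km.

    Bins are half-open ``[k*s, (k+1)*s)`` anchored at the origin, so a cell
    exactly on a boundary lands in the higher bin. Flows whose endpoints fall
    in the same bin become intra-cell and are excluded; bin coordinates are
    bin centers and bin population is the sum of member populations.
    """
    if cell_size <= 0:
        raise FlowHierError(f"cell_size must be positive, got {cell_size}")
    network.validate()

    def bin_of(cell: Cell) -> tuple[int, int]:
        return (math.floor(cell.x / cell_size), math.floor(cell.y / cell_size))

    assignment = {cid: bin_of(c) for cid, c in network.cells.items()}
    bins: dict[tuple[int, int], Cell] = {}
    pops: dict[tuple[int, int], list[float]] = {}
    for cid, b in assignment.items():
        pops.setdefault(b, [])
        p = network.cells[cid].population
        if p is not None:
            pops[b].append(p)
    for b, members in pops.items():
        bid = f"g{b[0]}_{b[1]}"
        bins[b] = Cell(
            bid,
            (b[0] + 0.5) * cell_size,
            (b[1] + 0.5) * cell_size,
            float(np.sum(members)) if members else None,
        )

    flows: dict[tuple[str, str], float] = {}
    dropped = 0.0
    for (o, d), w in network.flows.items():
        bo, bd = assignment[o], assignment[d]
        if bo == bd:
            dropped += w
            continue
        key = (bins[bo].id, bins[bd].id)
        flows[key] = flows.get(key, 0.0) + w

    out = TripNetwork(
        {c.id: c for c in bins.values()},
        flows,
        meta={"cell_size": cell_size, "dropped_same_bin_flow": dropped,
              "source_cells": network.n_cells},
    )
    return out.validate()
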