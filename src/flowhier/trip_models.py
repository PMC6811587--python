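"""Production-constrained trip-distribution models: gravity, radiation, PWO.

All three models take per-cell masses (populations, falling back to observed
out-trips when populations are absent) and per-cell out-trip totals O_i, and
allocate each origin's out-trips across destinations:

* gravity:   T_ij ∝ O_i · m_j^β · f(d_ij), with f either exp(-d/λ) or d^-γ;
* radiation: T_ij ∝ O_i · m_i m_j / ((m_i + s_ij)(m_i + m_j + s_ij)), where
  s_ij is the mass strictly inside the circle of radius d_ij around the
  origin, excluding both endpoints; renormalized per origin so the production
  constraint holds exactly on a finite set of cells;
* PWO (population-weighted opportunities):
  T_ij ∝ O_i · m_j (1/S_ji - 1/M), where S_ji is the mass inside the circle
  centered on the *destination* j with radius d_ji (j included, i excluded;
  strict-distance convention, configurable) and M is the total mass.

Each model returns a :class:`TripNetwork`, so the hierarchy pipeline runs on
model output exactly as on observed flows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import AllocationError, FlowHierError
from .hierarchy import HierarchyResult, city_phi
from .network_io import Cell, TripNetwork

#: floor for the distance between distinct cells that share coordinates (km)
MIN_DISTANCE_KM = 1e-9


@dataclass(frozen=True)
class ModelConfig:
    """Trip-model choice and parameters.

    ``mass_exponent`` β is the gravity destination-mass exponent (1 linear,
    2 quadratic); ``deterrence`` selects exp(-d/scale) or d**(-scale);
    ``pwo_inclusive_ties`` switches the PWO circle to include cells exactly
    at the origin's distance (a known literature ambiguity).
    """

    model: str = "gravity"
    mass_exponent: float = 1.0
    deterrence: str = "exponential"
    deterrence_scale: float = 5.0
    pwo_inclusive_ties: bool = False

    def __post_init__(self):
        if self.model not in ("gravity", "radiation", "pwo"):
            raise FlowHierError(f"unknown trip model {self.model!r}")
        if self.mass_exponent < 0:
            raise FlowHierError("mass_exponent must be >= 0")
        if self.deterrence not in ("exponential", "power"):
            raise FlowHierError(f"unknown deterrence {self.deterrence!r}")
        if self.deterrence_scale <= 0:
            raise FlowHierError("deterrence_scale must be > 0")


def _masses(cells: list[Cell], out_trips: dict[str, float]) -> np.ndarray:
    """Cell masses: populations when present, observed out-trips otherwise."""
    if all(c.population is not None for c in cells):
        return np.array([c.population for c in cells], dtype=float)
    return np.array([out_trips.get(c.id, 0.0) for c in cells], dtype=float)


def _distance_matrix(cells: list[Cell]) -> np.ndarray:
    xy = np.array([[c.x, c.y] for c in cells])
    diff = xy[:, None, :] - xy[None, :, :]
    D = np.sqrt((diff ** 2).sum(axis=-1))
    off = ~np.eye(len(cells), dtype=bool)
    if (D[off] < MIN_DISTANCE_KM).any():
        warnings.warn(
            "distinct cells at (near-)zero distance; flooring to "
            f"{MIN_DISTANCE_KM} km", stacklevel=3,
        )
        D[off & (D < MIN_DISTANCE_KM)] = MIN_DISTANCE_KM
    return D


def _network_from_matrix(cells: list[Cell], T: np.ndarray,
                         meta: dict) -> TripNetwork:
    ids = [c.id for c in cells]
    flows = {}
    src, dst = np.nonzero(T)
    for i, j in zip(src.tolist(), dst.tolist()):
        if i != j:
            flows[(ids[i], ids[j])] = float(T[i, j])
    return TripNetwork({c.id: c for c in cells}, flows, meta=meta).validate()


def _allocate(weights: np.ndarray, O: np.ndarray, model: str) -> np.ndarray:
    """Scale non-negative destination weights to per-origin totals O_i."""
    np.fill_diagonal(weights, 0.0)
    row = weights.sum(axis=1)
    starved = (O > 0) & (row <= 0)
    if starved.any():
        raise AllocationError(
            f"{model}: origins with positive out-trips but no positive-weight "
            f"destination at rows {np.nonzero(starved)[0].tolist()}"
        )
    T = np.zeros_like(weights)
    ok = row > 0
    T[ok] = weights[ok] * (O[ok] / row[ok])[:, None]
    return T


def gravity_flows(cells: list[Cell], out_trips: dict[str, float],
                  config: ModelConfig) -> TripNetwork:
    """Production-constrained gravity model with configurable mass exponent
    and deterrence function."""
    m = _masses(cells, out_trips)
    if (m > 0).sum() < 2:
        raise AllocationError("gravity needs at least two positive-mass cells")
    D = _distance_matrix(cells)
    if config.deterrence == "exponential":
        f = np.exp(-D / config.deterrence_scale)
    else:
        with np.errstate(divide="ignore"):
            f = D.astype(float) ** (-config.deterrence_scale)
        np.fill_diagonal(f, 0.0)
    W = (m[None, :] ** config.mass_exponent) * f
    O = np.array([out_trips.get(c.id, 0.0) for c in cells])
    T = _allocate(W, O, "gravity")
    return _network_from_matrix(cells, T, {"model": "gravity",
                                           "config": config})


def radiation_flows(cells: list[Cell],
                    out_trips: dict[str, float]) -> TripNetwork:
    """Parameter-free radiation model with per-origin renormalization.

    The intervening mass s_ij counts cells strictly closer to the origin than
    the destination (ties excluded), not counting either endpoint.
    """
    m = _masses(cells, out_trips)
    if (m > 0).sum() < 2:
        raise AllocationError("radiation needs at least two positive-mass cells")
    n = len(cells)
    D = _distance_matrix(cells)
    W = np.zeros((n, n))
    for i in range(n):
        others = np.arange(n) != i
        d = D[i, others]
        mm = m[others]
        order = np.argsort(d, kind="stable")
        d_sorted = d[order]
        cum = np.concatenate([[0.0], np.cumsum(mm[order])])
        # mass strictly inside radius d_ij around i (excludes i; excludes j
        # because d_jj is not < d_ij)
        k = np.searchsorted(d_sorted, d, side="left")
        s = cum[k]
        denom = (m[i] + s) * (m[i] + mm + s)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, m[i] * mm / denom, 0.0)
        W[i, others] = p
    O = np.array([out_trips.get(c.id, 0.0) for c in cells])
    T = _allocate(W, O, "radiation")
    return _network_from_matrix(cells, T, {"model": "radiation"})


def pwo_flows(cells: list[Cell], out_trips: dict[str, float],
              config: ModelConfig | None = None) -> TripNetwork:
    """Population-weighted-opportunities model.

    Destination attraction is m_j (1/S_ji - 1/M) with S_ji the mass inside
    the circle centered on destination j of radius d_ji. By default the
    circle is strict (cells at exactly the origin's distance excluded, hence
    the origin itself excluded); set ``pwo_inclusive_ties`` to include ties.
    """
    config = config or ModelConfig(model="pwo")
    m = _masses(cells, out_trips)
    M = m.sum()
    if (m > 0).sum() < 2:
        raise AllocationError("pwo needs at least two positive-mass cells")
    if (m >= M).any():
        raise AllocationError("pwo requires total mass above any single cell")
    n = len(cells)
    D = _distance_matrix(cells)
    side = "right" if config.pwo_inclusive_ties else "left"
    A = np.zeros((n, n))  # A[i, j] = attraction of destination j for origin i
    for j in range(n):
        d_from_j = D[j]  # includes d_jj = 0
        order = np.argsort(d_from_j, kind="stable")
        d_sorted = d_from_j[order]
        cum = np.concatenate([[0.0], np.cumsum(m[order])])
        k = np.searchsorted(d_sorted, d_from_j, side=side)
        S = cum[k]  # mass with d(j, .) < d(j, i); includes j itself
        if config.pwo_inclusive_ties:
            S = S - m  # inclusive circle would count the origin; remove it
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(S > 0, m[j] * (1.0 / S - 1.0 / M), 0.0)
        a = np.maximum(a, 0.0)
        A[:, j] = a
    O = np.array([out_trips.get(c.id, 0.0) for c in cells])
    T = _allocate(A, O, "pwo")
    return _network_from_matrix(cells, T, {"model": "pwo", "config": config})


def model_flows(cells: list[Cell], out_trips: dict[str, float],
                config: ModelConfig) -> TripNetwork:
    """Dispatch to the configured trip model."""
    if config.model == "gravity":
        return gravity_flows(cells, out_trips, config)
    if config.model == "radiation":
        return radiation_flows(cells, out_trips)
    return pwo_flows(cells, out_trips, config)


def model_phi(cells: list[Cell], out_trips: dict[str, float],
              config: ModelConfig, min_cells: int = 1) -> HierarchyResult:
    """Estimate Φ from model-generated flows: run the chosen trip model on
    (masses, out-trips), then the full hotspot/hierarchy pipeline."""
    network = model_flows(cells, out_trips, config)
    result = city_phi(network, min_cells=min_cells)
    result.meta.update({"trip_model": config.model, "model_config": config})
    return result
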