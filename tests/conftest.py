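import numpy as np
import pytest
from hypothesis import settings

from flowhier import Cell, TripNetwork

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def triangle_network():
    """Three cells with flows A->B:2, A->C:3, B->C:1."""
    cells = {
        "A": Cell("A", 0.0, 0.0, 100.0),
        "B": Cell("B", 1.0, 0.0, 50.0),
        "C": Cell("C", 0.0, 1.0, 10.0),
    }
    flows = {("A", "B"): 2.0, ("A", "C"): 3.0, ("B", "C"): 1.0}
    return TripNetwork(cells, flows)


def random_network(rng: np.random.Generator, n_cells: int = 30,
                   density: float = 0.3, with_population: bool = True):
    """A random valid TripNetwork for property tests."""
    cells = {}
    xy = rng.uniform(0, 50, size=(n_cells, 2))
    for k in range(n_cells):
        pop = float(rng.uniform(1, 1000)) if with_population else None
        cells[f"n{k}"] = Cell(f"n{k}", float(xy[k, 0]), float(xy[k, 1]), pop)
    flows = {}
    ids = list(cells)
    for i in ids:
        for j in ids:
            if i != j and rng.uniform() < density:
                flows[(i, j)] = float(rng.uniform(0.1, 100))
    if not flows:  # guarantee validity
        flows[(ids[0], ids[1])] = 1.0
    return TripNetwork(cells, flows)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def network_files(tmp_path, triangle_network):
    from flowhier import write_network

    edges = tmp_path / "edges.csv"
    cells = tmp_path / "cells.csv"
    write_network(triangle_network, edges, cells)
    return edges, cells
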