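import math

import numpy as np
import pytest

from flowhier import (
    AllocationError,
    Cell,
    FlowHierError,
    ModelConfig,
    gravity_flows,
    model_phi,
    outflows,
    pwo_flows,
    radiation_flows,
)
from flowhier.synthetic_city import CityConfig, generate_city


def line_cells(masses, spacing=1.0):
    return [Cell(f"c{k}", k * spacing, 0.0, float(m))
            for k, m in enumerate(masses)]


def production_totals(net):
    return outflows(net)


class TestGravity:
    def test_two_cells_send_everything_across(self):
        cells = line_cells([5, 5])
        out = {"c0": 10.0, "c1": 4.0}
        net = gravity_flows(cells, out, ModelConfig())
        assert net.flows[("c0", "c1")] == pytest.approx(10.0)
        assert net.flows[("c1", "c0")] == pytest.approx(4.0)

    def test_collinear_exponential_split(self):
        """Origin at 0 with equal-mass destinations at 1 and 2 km splits
        its out-trips in proportion e^-1 : e^-2 for lambda = 1."""
        cells = line_cells([1, 1, 1])
        out = {"c0": 6.0, "c1": 0.0, "c2": 0.0}
        net = gravity_flows(cells, out,
                            ModelConfig(deterrence_scale=1.0))
        ratio = net.flows[("c0", "c1")] / net.flows[("c0", "c2")]
        assert ratio == pytest.approx(math.e)
        assert net.flows[("c0", "c1")] + net.flows[("c0", "c2")] == \
            pytest.approx(6.0)

    def test_power_deterrence(self):
        cells = line_cells([1, 1, 1])
        out = {"c0": 3.0, "c1": 0.0, "c2": 0.0}
        net = gravity_flows(cells, out,
                            ModelConfig(deterrence="power",
                                        deterrence_scale=2.0))
        assert net.flows[("c0", "c1")] / net.flows[("c0", "c2")] == \
            pytest.approx(4.0)

    def test_large_lambda_limit_is_mass_proportional(self):
        """As lambda -> infinity the exponential kernel flattens and flows
        become proportional to destination mass alone."""
        cells = line_cells([2, 3, 5])
        out = {"c0": 8.0, "c1": 0.0, "c2": 0.0}
        net = gravity_flows(cells, out,
                            ModelConfig(deterrence_scale=1e9))
        assert net.flows[("c0", "c1")] == pytest.approx(8.0 * 3 / 8, rel=1e-6)
        assert net.flows[("c0", "c2")] == pytest.approx(8.0 * 5 / 8, rel=1e-6)

    def test_no_destination_is_allocation_error(self):
        cells = [Cell("a", 0, 0, 1.0), Cell("b", 1, 0, 0.0)]
        with pytest.raises(AllocationError):
            gravity_flows(cells, {"a": 5.0, "b": 0.0}, ModelConfig())


class TestRadiation:
    def test_two_isolated_cells(self):
        cells = line_cells([2, 3])
        net = radiation_flows(cells, {"c0": 7.0, "c1": 0.0})
        assert net.flows[("c0", "c1")] == pytest.approx(7.0)

    def test_three_cell_intervening_mass(self):
        """With unit masses at distances 1 and 2 from the origin, the far
        destination is screened by s = 1 intervening unit."""
        cells = line_cells([1, 1, 1])
        net = radiation_flows(cells, {"c0": 1.0, "c1": 0.0, "c2": 0.0})
        # unnormalized weights: near 1/(1*2) = 0.5, far 1/(2*3) = 1/6
        expected_near = 0.5 / (0.5 + 1 / 6)
        assert net.flows[("c0", "c1")] == pytest.approx(expected_near)
        assert net.flows[("c0", "c2")] == pytest.approx(1 - expected_near)

    def test_matches_brute_force_formula(self, rng):
        n = 25
        cells = [Cell(f"c{k}", float(x), float(y), float(m))
                 for k, (x, y, m) in enumerate(
                     zip(rng.uniform(0, 10, n), rng.uniform(0, 10, n),
                         rng.uniform(1, 50, n)))]
        out = {c.id: float(rng.uniform(0, 10)) for c in cells}
        net = radiation_flows(cells, out)
        # independent O(n^3) evaluation
        for i, ci in enumerate(cells):
            weights = {}
            for j, cj in enumerate(cells):
                if i == j:
                    continue
                d_ij = math.hypot(ci.x - cj.x, ci.y - cj.y)
                s = sum(ck.population for k, ck in enumerate(cells)
                        if k not in (i, j)
                        and math.hypot(ci.x - ck.x, ci.y - ck.y) < d_ij)
                weights[cj.id] = (ci.population * cj.population /
                                  ((ci.population + s) *
                                   (ci.population + cj.population + s)))
            total = sum(weights.values())
            for cj_id, w in weights.items():
                expected = out[ci.id] * w / total
                got = net.flows.get((ci.id, cj_id), 0.0)
                assert got == pytest.approx(expected, abs=1e-10)

    def test_relabeling_leaves_flow_multiset_unchanged(self, rng):
        n = 12
        xs, ys = rng.uniform(0, 5, n), rng.uniform(0, 5, n)
        ms = rng.uniform(1, 10, n)
        out_vals = rng.uniform(1, 5, n)
        cells = [Cell(f"c{k}", xs[k], ys[k], ms[k]) for k in range(n)]
        out = {f"c{k}": float(out_vals[k]) for k in range(n)}
        net = radiation_flows(cells, out)
        perm = rng.permutation(n)
        cells2 = [Cell(f"z{k}", xs[p], ys[p], ms[p])
                  for k, p in enumerate(perm)]
        out2 = {f"z{k}": float(out_vals[p]) for k, p in enumerate(perm)}
        net2 = radiation_flows(cells2, out2)
        a = sorted(np.round(sorted(net.flows.values()), 9))
        b = sorted(np.round(sorted(net2.flows.values()), 9))
        assert a == pytest.approx(b)


class TestPWO:
    def test_two_cells_single_destination(self):
        cells = line_cells([2, 3])
        net = pwo_flows(cells, {"c0": 4.0, "c1": 0.0})
        assert net.flows[("c0", "c1")] == pytest.approx(4.0)

    def test_square_equidistant_destinations_split_equally(self):
        """On a unit square with equal masses the two side-adjacent
        destinations are symmetric and receive identical flow; the diagonal
        one is screened by more intervening mass and receives less."""
        cells = [Cell("a", 0, 0, 1.0), Cell("b", 1, 0, 1.0),
                 Cell("c", 0, 1, 1.0), Cell("d", 1, 1, 1.0)]
        net = pwo_flows(cells, {"a": 1.0, "b": 0.0, "c": 0.0, "d": 0.0})
        assert net.flows[("a", "b")] == pytest.approx(net.flows[("a", "c")])
        assert net.flows[("a", "d")] < net.flows[("a", "b")]

    def test_matches_brute_force_circle_counting(self, rng):
        n = 30
        cells = [Cell(f"c{k}", float(x), float(y), float(m))
                 for k, (x, y, m) in enumerate(
                     zip(rng.uniform(0, 20, n), rng.uniform(0, 20, n),
                         rng.uniform(1, 100, n)))]
        out = {c.id: float(rng.uniform(1, 10)) for c in cells}
        M = sum(c.population for c in cells)
        net = pwo_flows(cells, out)
        for i, ci in enumerate(cells):
            attr = {}
            for j, cj in enumerate(cells):
                if i == j:
                    continue
                d_ji = math.hypot(cj.x - ci.x, cj.y - ci.y)
                S = sum(ck.population for k, ck in enumerate(cells)
                        if k != i
                        and math.hypot(cj.x - ck.x, cj.y - ck.y) < d_ji)
                attr[cj.id] = cj.population * (1.0 / S - 1.0 / M)
            total = sum(attr.values())
            for cj_id, a in attr.items():
                assert net.flows.get((ci.id, cj_id), 0.0) == \
                    pytest.approx(out[ci.id] * a / total, abs=1e-10)


class TestProductionConstraint:
    @pytest.mark.parametrize("model", ["gravity", "radiation", "pwo"])
    def test_out_totals_match_exactly(self, model, rng):
        n = 20
        cells = [Cell(f"c{k}", float(x), float(y), float(m))
                 for k, (x, y, m) in enumerate(
                     zip(rng.uniform(0, 10, n), rng.uniform(0, 10, n),
                         rng.uniform(1, 50, n)))]
        out = {c.id: float(rng.uniform(0, 20)) for c in cells}
        config = ModelConfig(model=model)
        from flowhier import model_flows
        net = model_flows(cells, out, config)
        got = production_totals(net)
        for cid, o in out.items():
            assert got[cid] == pytest.approx(o, rel=1e-10)
        assert all(w >= 0 for w in net.flows.values())
        assert all(o != d for (o, d) in net.flows)


class TestModelPhi:
    def test_deterministic(self):
        net = generate_city(CityConfig(grid_side=10, seed=5))
        cells = list(net.cells.values())
        out = outflows(net)
        r1 = model_phi(cells, out, ModelConfig())
        r2 = model_phi(cells, out, ModelConfig())
        assert r1.phi == r2.phi
        assert r1.L == r2.L

    def test_radiation_at_least_as_hierarchical_as_linear_gravity(self):
        """The radiation model's nonlinearity concentrates flow between top
        hotspot levels, so its Φ estimate sits above linear gravity's."""
        wins = 0
        for seed in range(5):
            net = generate_city(CityConfig(grid_side=14, seed=seed))
            cells = list(net.cells.values())
            out = outflows(net)
            phi_rad = model_phi(cells, out, ModelConfig(model="radiation")).phi
            phi_grav = model_phi(cells, out, ModelConfig(model="gravity")).phi
            wins += phi_rad >= phi_grav
        assert wins >= 4

    def test_invalid_model_rejected(self):
        with pytest.raises(FlowHierError):
            ModelConfig(model="intervening")
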