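"""Unit tests for the growing lattice: initialization, BMU search, growth
topology, weight updates, error bookkeeping and schedule decays."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import igsom
from igsom.gsom import PHI_FLOOR

from conftest import make_map, random_connected_map


class TestInitialize:
    def test_initial_block(self):
        m = igsom.GrowingMap.initialize(3, seed=7)
        assert set(m.nodes) == {(0, 0), (0, 1), (1, 0), (1, 1)}
        for node in m:
            assert node.weight.shape == (3,)
            assert ((node.weight >= 0) & (node.weight <= 1)).all()
            assert node.accumulated_error == 0.0
        assert m.boundary_ratio() == 1.0

    def test_seeded_determinism(self):
        a = igsom.GrowingMap.initialize(5, seed=3)
        b = igsom.GrowingMap.initialize(5, seed=3)
        for pa, pb in zip(a, b):
            assert (pa.weight == pb.weight).all()

    def test_invalid_dimension(self):
        with pytest.raises(ValueError):
            igsom.GrowingMap(0)


class TestFindBmu:
    def test_two_node_nearest(self):
        m = make_map({(0, 0): [0.0, 0.0], (0, 1): [1.0, 1.0]})
        pos, dist = m.find_bmu(np.array([0.1, 0.1]))
        assert pos == (0, 0)
        assert dist == pytest.approx(math.sqrt(0.02))

    def test_exact_match(self):
        m = make_map({(0, 0): [0.2, 0.8], (1, 1): [0.5, 0.5]})
        pos, dist = m.find_bmu(np.array([0.5, 0.5]))
        assert pos == (1, 1) and dist == 0.0

    def test_tie_breaks_lexicographic(self):
        m = make_map({(1, 0): [0.0], (0, 5): [1.0]})
        pos, _ = m.find_bmu(np.array([0.5]))
        assert pos == (0, 5)

    def test_dimension_mismatch(self):
        m = igsom.GrowingMap.initialize(3, seed=0)
        with pytest.raises(ValueError):
            m.find_bmu(np.zeros(4))

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(42)
        m = random_connected_map(rng, 30, 4)
        for _ in range(100):
            x = rng.random(4)
            pos, dist = m.find_bmu(x)
            # independent oracle: exhaustive linear scan, lexicographic ties
            best = min(
                ((np.linalg.norm(node.weight - x), node.position) for node in m),
                key=lambda t: (t[0], t[1]),
            )
            assert pos == best[1]
            assert dist == pytest.approx(best[0])


class TestBoundary:
    def test_initial_block_all_boundary(self):
        m = igsom.GrowingMap.initialize(2, seed=0)
        assert all(m.is_boundary(p) for p in m.nodes)

    def test_center_of_full_3x3_is_interior(self):
        m = make_map({(r, c): [0.5] for r in range(3) for c in range(3)})
        assert not m.is_boundary((1, 1))
        assert all(m.is_boundary(p) for p in m.nodes if p != (1, 1))

    def test_gap_makes_neighbor_boundary(self):
        cells = {(r, c): [0.5] for r in range(3) for c in range(3) if (r, c) != (0, 0)}
        m = make_map(cells)
        # (1, 1) gained a free neighbour through the missing corner... it did not:
        # (0,0) is adjacent to (0,1) and (1,0), not to the centre
        assert m.is_boundary((0, 1)) and m.is_boundary((1, 0))
        assert not m.is_boundary((1, 1))

    def test_unoccupied_raises(self):
        m = igsom.GrowingMap.initialize(2, seed=0)
        with pytest.raises(ValueError):
            m.is_boundary((9, 9))


class TestGrow:
    def test_corner_growth_positions(self):
        m = igsom.GrowingMap.initialize(2, seed=1)
        added = m.grow((0, 0))
        assert added == [(-1, 0), (0, -1)]
        assert len(m) == 6
        assert m.nodes[(0, 0)].accumulated_error == 0.0
        for pos in added:
            assert m.nodes[pos].accumulated_error == 0.0

    def test_single_free_neighbor(self):
        cells = {(r, c): [0.5] for r in range(3) for c in range(3) if (r, c) != (0, 1)}
        m = make_map(cells)
        added = m.grow((1, 1))
        assert added == [(0, 1)]

    def test_boundary_status_consistent_after_growth(self):
        m = igsom.GrowingMap.initialize(2, seed=2)
        added = m.grow((1, 1))
        for pos in added:
            # oracle: recheck adjacency exhaustively
            free = [p for p in igsom.adjacent_positions(pos) if p not in m.nodes]
            assert m.is_boundary(pos) == bool(free)

    def test_non_boundary_raises(self):
        m = make_map({(r, c): [0.5] for r in range(3) for c in range(3)})
        with pytest.raises(ValueError):
            m.grow((1, 1))

    def test_connectivity_and_monotone_count(self):
        rng = np.random.default_rng(5)
        m = igsom.GrowingMap.initialize(2, seed=5)
        for _ in range(25):
            boundary = sorted(p for p in m.nodes if m.is_boundary(p))
            n_before = len(m)
            m.grow(boundary[rng.integers(len(boundary))])
            assert len(m) > n_before
        # 4-connectivity: BFS from any node reaches all
        seen = {next(iter(m.nodes))}
        stack = list(seen)
        while stack:
            for p in igsom.adjacent_positions(stack.pop()):
                if p in m.nodes and p not in seen:
                    seen.add(p)
                    stack.append(p)
        assert seen == set(m.nodes)


class TestNewNodeWeight:
    def test_opposite_extrapolation(self):
        m = make_map({(0, 0): [0.6], (0, 1): [0.4]})
        w = m.new_node_weight((0, 0), (0, -1))
        assert w == pytest.approx([0.8])

    def test_clamped_extrapolation(self):
        m = make_map({(0, 0): [0.9], (0, 1): [0.1]})
        assert m.new_node_weight((0, 0), (0, -1)) == pytest.approx([1.0])

    def test_isolated_bmu_copies(self):
        m = make_map({(0, 0): [0.3, 0.7]})
        assert m.new_node_weight((0, 0), (1, 0)) == pytest.approx([0.3, 0.7])

    def test_occupied_target_raises(self):
        m = igsom.GrowingMap.initialize(1, seed=0)
        with pytest.raises(ValueError):
            m.new_node_weight((0, 0), (0, 1))


class TestUpdateWeights:
    def test_bmu_full_step(self):
        m = make_map({(0, 0): [0.0]})
        m.update_weights((0, 0), np.array([1.0]), learning_rate=0.5, neighborhood_size=2)
        assert m.nodes[(0, 0)].weight == pytest.approx([0.5])

    def test_neighbor_gaussian_attenuation(self):
        m = make_map({(0, 0): [0.0], (0, 1): [0.0]})
        m.update_weights((0, 0), np.array([1.0]), learning_rate=0.5, neighborhood_size=2)
        expected = 0.5 * math.exp(-1.0 / 8.0)  # d=1, sigma=2
        assert m.nodes[(0, 1)].weight == pytest.approx([expected])
        assert expected == pytest.approx(0.44124845, abs=1e-6)

    def test_weights_stay_in_unit_interval(self):
        rng = np.random.default_rng(8)
        m = random_connected_map(rng, 20, 3)
        for _ in range(50):
            x = rng.random(3)
            bmu, _ = m.find_bmu(x)
            m.update_weights(bmu, x, learning_rate=1.0, neighborhood_size=1.5)
        for node in m:
            assert ((node.weight >= 0) & (node.weight <= 1)).all()

    def test_bmu_strictly_approaches_input(self):
        rng = np.random.default_rng(9)
        m = random_connected_map(rng, 12, 4)
        x = rng.random(4)
        bmu, before = m.find_bmu(x)
        m.update_weights(bmu, x, learning_rate=0.3, neighborhood_size=1.0)
        assert np.linalg.norm(m.nodes[bmu].weight - x) < before


class TestErrors:
    def test_accumulation_is_additive(self):
        m = igsom.GrowingMap.initialize(2, seed=0)
        m.accumulate_error((0, 0), 1.5)
        assert m.nodes[(0, 0)].accumulated_error == 1.5
        m.accumulate_error((0, 0), 1.0)
        m.accumulate_error((0, 0), 2.0)
        assert m.nodes[(0, 0)].accumulated_error == 4.5
        m.accumulate_error((0, 0), 0.0)
        assert m.nodes[(0, 0)].accumulated_error == 4.5
        with pytest.raises(ValueError):
            m.accumulate_error((0, 0), -0.1)

    @pytest.mark.parametrize(
        "t_grow, gamma, e_bmu, expected_bmu, expected_gain",
        [(2.0, 0.5, 3.0, 1.0, 1.0), (1.0, 0.5, 1.4, 0.5, 0.5)],
    )
    def test_distribution_arithmetic(self, t_grow, gamma, e_bmu, expected_bmu, expected_gain):
        m = make_map({(r, c): [0.5] for r in range(3) for c in range(3)})
        m.nodes[(1, 1)].accumulated_error = e_bmu
        params = igsom.PhaseParams(growth_threshold=t_grow, gamma=gamma)
        total_before = sum(n.accumulated_error for n in m)
        m.distribute_error((1, 1), params)
        assert m.nodes[(1, 1)].accumulated_error == expected_bmu
        for pos in igsom.adjacent_positions((1, 1)):
            assert m.nodes[pos].accumulated_error == expected_gain
        # exact total bookkeeping: (T/2 - E_old) + 4 * gamma * T
        total_after = sum(n.accumulated_error for n in m)
        assert total_after - total_before == pytest.approx(
            (t_grow / 2 - e_bmu) + 4 * gamma * t_grow
        )

    def test_distribution_on_boundary_raises(self):
        m = igsom.GrowingMap.initialize(2, seed=0)
        with pytest.raises(ValueError):
            m.distribute_error((0, 0), igsom.PhaseParams())


class TestDecays:
    def test_learning_rate_at_four_nodes(self):
        m = igsom.GrowingMap.initialize(2, seed=0)
        params = igsom.PhaseParams(alpha=0.9)
        assert igsom.decay_learning_rate(0.5, m, params) == pytest.approx(0.0225)

    def test_learning_rate_at_many_nodes(self):
        m = make_map({(0, c): [0.5] for c in range(38)})
        params = igsom.PhaseParams(alpha=0.9)
        # phi(38) = 1 - 3.8/38 = 0.9
        assert igsom.decay_learning_rate(1.0, m, params) == pytest.approx(0.81)

    def test_phi_floor_when_tiny_map(self, caplog):
        m = make_map({(0, 0): [0.5], (0, 1): [0.5]})  # n=2 < Q
        params = igsom.PhaseParams(alpha=0.9)
        out = igsom.decay_learning_rate(0.5, m, params)
        assert out == pytest.approx(0.9 * PHI_FLOOR * 0.5)

    def test_neighborhood_decay(self):
        params = igsom.PhaseParams(beta=0.9)
        assert igsom.decay_neighborhood(2.0, params) == pytest.approx(1.8)
        sigma = 2.0
        for _ in range(7):
            sigma = igsom.decay_neighborhood(sigma, params)
        assert sigma == pytest.approx(2 * 0.9**7)
        assert sigma < 1.0  # the inner loop terminates

    def test_degenerate_beta_rejected(self):
        with pytest.raises(ValueError):
            igsom.PhaseParams(beta=1.0)


@settings(deadline=None, max_examples=30)
@given(st.integers(0, 2**16), st.integers(5, 40))
def test_bmu_oracle_property(seed, n_nodes):
    """find_bmu agrees with an exhaustive linear scan for arbitrary maps."""
    rng = np.random.default_rng(seed)
    m = random_connected_map(rng, n_nodes, 3)
    x = rng.random(3)
    pos, dist = m.find_bmu(x)
    best = min(
        ((np.linalg.norm(node.weight - x), node.position) for node in m),
        key=lambda t: (t[0], t[1]),
    )
    assert pos == best[1] and dist == pytest.approx(best[0])
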