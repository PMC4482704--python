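"""Dispersal kernels, network reachability, least-cost distance, thresholds."""

import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from riverscape import (Barrier, DispersalKernel, ModeConfig,
                        RiverNetworkGraph, kernel_quantile, least_cost,
                        least_cost_raster, network_reachable, recolonize_fish,
                        recolonize_invert, source_threshold)

from conftest import line_network, random_tree_network


def oracle_kernel_quantile(k, mass, grid_max=None, n=2_000_001):
    """Dense-grid CDF inversion of the absolute-displacement mixture."""
    hi = grid_max or 12 * max(k.sigma_stat, k.sigma_mob)
    xs = np.linspace(0, hi, n)
    cdf = (1 - k.p_mobile) * (2 * stats.norm.cdf(xs / k.sigma_stat) - 1) + \
        k.p_mobile * (2 * stats.norm.cdf(xs / k.sigma_mob) - 1)
    return xs[np.searchsorted(cdf, mass)]


def enumerate_least_cost(graph, sources, friction):
    """Exhaustive simple-path enumeration oracle on a small undirected graph."""
    best = {s: 0.0 for s in sources}

    def edge_cost(u, v):
        f = friction if isinstance(friction, (int, float)) else \
            0.5 * (friction[u] + friction[v])
        return graph[u][v]["dist"] * f

    def dfs(node, cost, visited):
        if cost < best.get(node, math.inf):
            best[node] = cost
        for nb in graph[node]:
            if nb not in visited:
                dfs(nb, cost + edge_cost(node, nb), visited | {nb})

    for s in sources:
        dfs(s, 0.0, {s})
    return best


class TestKernelQuantile:
    def test_single_component_closed_form(self):
        k = DispersalKernel(sigma_stat=100.0, sigma_mob=100.0, p_mobile=0.0)
        assert kernel_quantile(k, 0.99) == pytest.approx(257.58, abs=0.1)

    def test_degenerate_mixture_independent_of_share(self):
        base = kernel_quantile(DispersalKernel(80.0, 80.0, 0.0))
        for p in (0.2, 0.5, 0.9):
            assert kernel_quantile(DispersalKernel(80.0, 80.0, p)) == \
                pytest.approx(base, rel=1e-9)

    def test_matches_dense_cdf_oracle(self):
        k = DispersalKernel(sigma_stat=50.0, sigma_mob=500.0, p_mobile=2 / 3)
        assert kernel_quantile(k, 0.99) == pytest.approx(
            oracle_kernel_quantile(k, 0.99), abs=0.1)

    def test_strictly_increasing_in_mass_and_sigma(self):
        k = DispersalKernel(100.0, 1000.0, 0.3)
        q1, q2 = kernel_quantile(k, 0.90), kernel_quantile(k, 0.99)
        assert q1 < q2
        bigger = DispersalKernel(100.0, 1500.0, 0.3)
        assert kernel_quantile(k, 0.99) < kernel_quantile(bigger, 0.99)

    def test_invalid_mass(self):
        with pytest.raises(ValueError):
            kernel_quantile(DispersalKernel(1, 1, 0), 1.0)

    def test_diffusive_multi_year_scaling(self):
        k = DispersalKernel(100.0, 1000.0, 0.3)
        k3 = k.scaled(3.0)
        assert k3.sigma_stat == pytest.approx(100 * math.sqrt(3))
        assert k.scaled(3.0, "linear").sigma_mob == pytest.approx(3000.0)


class TestNetworkReachable:
    def test_all_sources_reach_everything(self):
        net = line_network(1000, dx=10)
        reached = network_reachable(net, set(net.cells), 0.0)
        assert reached == set(net.cells)

    def test_line_distance_truncation(self):
        net = line_network(1000, dx=10)
        source = {(1, 0, 99)}  # downstream end cell
        reached = network_reachable(net, source, 400.0)
        share = 100 * net.reachable_length(reached) / net.total_length
        assert share == pytest.approx(40.0, abs=100 * net.dx / net.total_length)

    def test_impassable_barrier_truncates_upstream(self):
        barrier = Barrier(edge=(1, 0), position_m=900.0, passability_up=0.0)
        net = line_network(1000, dx=10, barriers=[barrier])
        reached = network_reachable(net, {(1, 0, 99)}, 2000.0)
        share = 100 * net.reachable_length(reached) / net.total_length
        assert share == pytest.approx(10.0, abs=100 * net.dx / net.total_length)

    def test_downstream_traversal_of_barrier_allowed(self):
        barrier = Barrier(edge=(1, 0), position_m=500.0, passability_up=0.0)
        net = line_network(1000, dx=10, barriers=[barrier])
        # source at the upstream end: the whole line is reachable downstream
        reached = network_reachable(net, {(1, 0, 0)}, 2000.0)
        assert len(reached) == len(net.cells)

    def test_partial_passability_is_passable_in_binary_mode(self):
        barrier = Barrier(edge=(1, 0), position_m=500.0, passability_up=0.4)
        net = line_network(1000, dx=10, barriers=[barrier])
        reached = network_reachable(net, {(1, 0, 99)}, 2000.0)
        assert len(reached) == len(net.cells)
        blocked = network_reachable(net, {(1, 0, 99)}, 2000.0,
                                    passability_threshold=0.5)
        assert len(blocked) < len(net.cells)

    def test_monotone_in_distance(self, rng):
        net = random_tree_network(rng)
        src = {net.cells[0]}
        prev: set = set()
        for d in (100.0, 400.0, 1600.0, 1e6):
            cur = network_reachable(net, src, d)
            assert prev <= cur
            prev = cur

    def test_empty_sources_rejected(self):
        with pytest.raises(ValueError):
            network_reachable(line_network(), set(), 100.0)


class TestRecolonizeFish:
    def test_full_coverage_without_barriers(self, rng):
        net = random_tree_network(rng)
        k = DispersalKernel(1e5, 1e5, 0.0)
        res = recolonize_fish(net, {net.cells[0]}, k)
        assert res.share == pytest.approx(100.0)

    def test_equal_ci_kernels_zero_width(self):
        net = line_network(1000, dx=10)
        k = DispersalKernel(100.0, 300.0, 0.3)
        res = recolonize_fish(net, {(1, 0, 50)}, k, k, k)
        assert res.ci_low == res.share == res.ci_high

    def test_barriers_never_increase_share(self, rng):
        for _ in range(5):
            net = random_tree_network(rng)
            src = set(c for c in net.cells[::7]) or {net.cells[0]}
            k = DispersalKernel(300.0, 900.0, 0.3)
            base = recolonize_fish(net, src, k).share
            edges = list(net.graph.edges(data=True))
            u, v, data = edges[rng.integers(len(edges))]
            bar = Barrier((u, v), float(rng.uniform(0, data["length"])), 0.0)
            blocked = RiverNetworkGraph(
                [(a, b, d["length"]) for a, b, d in edges],
                dx=net.dx, barriers=net.barriers + [bar])
            assert recolonize_fish(blocked, src, k).share <= base + 1e-9


class TestLeastCost:
    def test_uniform_friction_on_line_equals_distance(self):
        net = line_network(1000, dx=10)
        costs = least_cost(net, {(1, 0, 0)}, friction=1.0)
        # cost from the most upstream cell grows linearly downstream
        assert costs[(1, 0, 50)] == pytest.approx(500.0)
        assert costs[(1, 0, 0)] == 0.0

    def test_friction_scales_cost(self):
        net = line_network(1000, dx=10)
        c1 = least_cost(net, {(1, 0, 0)}, friction=1.0)
        c3 = least_cost(net, {(1, 0, 0)}, friction=3.0)
        for cell, v in c1.items():
            assert c3[cell] == pytest.approx(3 * v)

    def test_five_node_graph_matches_path_enumeration(self):
        g = nx.Graph()
        edges = [(0, 1, 10), (1, 2, 5), (0, 2, 25), (2, 3, 8), (1, 3, 30),
                 (3, 4, 4)]
        for u, v, d in edges:
            g.add_edge(u, v, dist=float(d))
        friction = {0: 1.0, 1: 2.0, 2: 0.5, 3: 3.0, 4: 1.0}
        got = least_cost(g, [0], friction)
        expected = enumerate_least_cost(g, [0], friction)
        for node in g.nodes:
            assert got[node] == pytest.approx(expected[node])

    def test_random_small_graphs_match_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 13))
            g = nx.Graph()
            nodes = list(range(n))
            for i in range(1, n):     # random tree keeps it connected
                g.add_edge(i, int(rng.integers(0, i)),
                           dist=float(rng.uniform(1, 20)))
            for _ in range(int(rng.integers(0, 4))):   # a few extra edges
                u, v = rng.choice(n, size=2, replace=False)
                g.add_edge(int(u), int(v), dist=float(rng.uniform(1, 20)))
            friction = {i: float(rng.uniform(0.2, 3.0)) for i in nodes}
            sources = [0] if n < 6 else [0, n - 1]
            got = least_cost(g, sources, friction)
            expected = enumerate_least_cost(g, sources, friction)
            for node in nodes:
                assert got[node] == pytest.approx(expected[node])

    def test_raster_uniform_friction_distances(self):
        friction = np.ones((5, 7))
        sources = np.zeros((5, 7), dtype=bool)
        sources[2, 0] = True
        acc = least_cost_raster(friction, sources, cellsize=2.0)
        assert acc[2, 0] == 0.0
        assert acc[2, 6] == pytest.approx(12.0)         # straight run
        assert acc[0, 2] == pytest.approx(2 * 2 * math.sqrt(2))  # diagonal moves

    def test_raster_triangle_property(self, rng):
        friction = rng.uniform(0.5, 2.0, size=(8, 8))
        sources = np.zeros((8, 8), dtype=bool)
        sources[0, 0] = True
        acc = least_cost_raster(friction, sources)
        for r in range(8):
            for c in range(7):
                step = 0.5 * (friction[r, c] + friction[r, c + 1])
                assert abs(acc[r, c] - acc[r, c + 1]) <= step + 1e-9

    def test_disconnected_raster_cells_infinite(self):
        friction = np.ones((3, 3))
        friction[:, 1] = np.nan
        sources = np.zeros((3, 3), dtype=bool)
        sources[1, 0] = True
        acc = least_cost_raster(friction, sources)
        assert np.isinf(acc[1, 2])


def _modes(cons, prog):
    return [ModeConfig(m, 1.0, cons, prog)
            for m in ("aerial", "aquatic_upstream", "aquatic_downstream")]


class TestRecolonizeInvert:
    def test_zero_thresholds_reach_only_sources(self):
        net = line_network(1000, dx=10)
        src = {(1, 0, 10), (1, 0, 60)}
        res = recolonize_invert(net, src, _modes(0.0, 0.0))
        assert res.share == pytest.approx(100 * 2 * 10 / 1000)
        assert all(res.mode_counts[c] == 3 for c in src)

    def test_mode_count_three_when_all_modes_reach(self):
        net = line_network(200, dx=10)
        res = recolonize_invert(net, {(1, 0, 10)}, _modes(1e6, 1e6))
        # every mode reaches the source cell itself; the whole line is
        # covered once aerial (both directions) is in play
        assert res.mode_counts[(1, 0, 10)] == 3
        assert res.share == pytest.approx(100.0)

    def test_upstream_mode_respects_barriers(self):
        barrier = Barrier(edge=(1, 0), position_m=500.0, passability_up=0.0)
        net = line_network(1000, dx=10, barriers=[barrier])
        src = {(1, 0, 99)}
        res = recolonize_invert(net, src, _modes(1e6, 1e6))
        up_blocked = [c for c, k in res.mode_counts.items()
                      if c[2] < 50 and k > 0]
        # upstream half reached only by the barrier-ignoring aerial mode
        assert all(res.mode_counts[c] <= 1 for c in up_blocked)
        assert res.per_mode_share["aquatic_upstream"] == pytest.approx(
            50.0, abs=100 * net.dx / net.total_length)

    def test_downstream_mode_only_moves_downstream(self):
        net = line_network(1000, dx=10)
        res = recolonize_invert(net, {(1, 0, 50)},
                                [ModeConfig("aerial", 1.0, 0.0, 0.0),
                                 ModeConfig("aquatic_upstream", 1.0, 0.0, 0.0),
                                 ModeConfig("aquatic_downstream", 1.0, 1e6, 1e6)])
        reached = {c for c, k in res.mode_counts.items() if k > 0}
        assert all(c[2] >= 50 for c in reached)

    def test_conservative_never_exceeds_progressive(self, rng):
        for _ in range(8):
            net = random_tree_network(rng)
            src = {net.cells[int(rng.integers(len(net.cells)))]}
            modes = _modes(float(rng.uniform(50, 400)),
                           float(rng.uniform(400, 3000)))
            cons = recolonize_invert(net, src, modes, "conservative")
            prog = recolonize_invert(net, src, modes, "progressive")
            assert cons.share <= prog.share + 1e-9

    def test_scenario_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            ModeConfig("aerial", 1.0, 100.0, 50.0)


class TestSourceThreshold:
    def test_separable_classes(self):
        t, j = source_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert j == pytest.approx(2.0)
        assert t == pytest.approx(0.8)   # lowest candidate achieving J=2

    def test_tie_broken_toward_lowest_threshold(self):
        t, j = source_threshold([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert t == pytest.approx(0.35)
        assert j == pytest.approx(1.5)

    def test_matches_brute_force_on_random_data(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 40))
            p = rng.random(n)
            y = (rng.random(n) < 0.5).astype(int)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            t, j = source_threshold(p, y)
            # exhaustive check over all candidate thresholds
            best = max(
                ((tc, ((p >= tc) & (y == 1)).sum() / (y == 1).sum()
                  + ((p < tc) & (y == 0)).sum() / (y == 0).sum())
                 for tc in np.unique(p)),
                key=lambda z: (round(z[1], 12), -z[0]))
            assert j == pytest.approx(best[1])
            assert t == pytest.approx(best[0])

    def test_label_flip_consistency(self, rng):
        p = rng.random(20)
        y = (rng.random(20) < 0.5).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        t1, _ = source_threshold(p, y)
        t2, _ = source_threshold(p, 1 - y)
        assert 0 <= t1 <= 1 and 0 <= t2 <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            source_threshold([0.1, 0.9], [1, 1])
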