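"""Generalized correlation, contact filtering, graph building, Dijkstra
paths against a brute-force enumeration oracle."""

import itertools

import networkx as nx
import numpy as np
import pytest

from mdnetics.core import Selection, ensemble_from_arrays, select
from mdnetics.network import (CorrelationMatrix, OccupancyContactMap,
                              build_graph, correlation_difference,
                              generalized_correlation, ksg_mutual_information,
                              mi_matrix_knn, occupancy_contact_map,
                              replica_average, shortest_paths)
from mdnetics.synthetic import (GaussianEnsembleSpec, _bead_topology,
                                gen_gaussian_ensemble)


def gaussian_mi_3d(rho):
    """Closed form: I = -3/2 ln(1 - rho^2) for three independent
    per-dimension Gaussian pairs."""
    return -1.5 * np.log(1.0 - rho * rho)


class TestKSGEstimator:
    def _pair(self, rho, n=5000, seed=0):
        rng = np.random.default_rng(seed)
        z1 = rng.standard_normal((n, 3))
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal((n, 3))
        return z1, z2

    def test_independent_vectors_near_zero(self):
        x, y = self._pair(0.0, seed=1)
        assert ksg_mutual_information(x, y) < 0.02

    def test_gaussian_closed_form(self):
        x, y = self._pair(0.6, seed=2)
        expected = gaussian_mi_3d(0.6)  # 0.6694 nats
        assert ksg_mutual_information(x, y) == pytest.approx(expected, abs=0.08)

    def test_symmetry_exact(self):
        x, y = self._pair(0.4, n=800, seed=3)
        assert ksg_mutual_information(x, y) == ksg_mutual_information(y, x)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            ksg_mutual_information(np.zeros((5, 3)), np.zeros((5, 3)), k=6)


class TestGeneralizedCorrelation:
    def test_zero_mi_zero_r(self):
        c = generalized_correlation(np.zeros((3, 3)))
        off = c.r[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.0)
        np.testing.assert_allclose(np.diag(c.r), 1.0)

    def test_saturation(self):
        mi = np.full((2, 2), 50.0)
        c = generalized_correlation(mi)
        assert c.r[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_recovers_gaussian_rho(self):
        mi = np.array([[0.0, gaussian_mi_3d(0.6)], [gaussian_mi_3d(0.6), 0.0]])
        c = generalized_correlation(mi)
        assert c.r[0, 1] == pytest.approx(0.6, abs=1e-12)

    def test_negative_mi_rejected(self):
        with pytest.raises(ValueError):
            generalized_correlation(np.array([[0.0, -0.1], [-0.1, 0.0]]))

    def test_estimator_consistency_on_planted_pairs(self):
        """r_MI recovers |rho| within 0.05 on 3-D Gaussian ensembles."""
        for rho in (0.0, 0.6):
            ens = gen_gaussian_ensemble(GaussianEnsembleSpec(
                n_residues=2, correlations=([(0, 1, rho)] if rho else []),
                n_frames=5000, seed=int(rho * 10) + 1))
            sel = select(ens.topology, "all")
            mats = mi_matrix_knn(ens, sel, k=6, stride=1, superpose=False)
            c = generalized_correlation(mats[0])
            assert c.r[0, 1] == pytest.approx(rho, abs=0.05)


class TestOccupancyContactMap:
    def _ens(self, distances):
        pos = np.zeros((2, 3))
        top = _bead_topology(pos)
        coords = np.zeros((len(distances), 2, 3))
        coords[:, 1, 0] = distances
        return ensemble_from_arrays(top, [coords])

    def test_always_within_cutoff(self):
        m = occupancy_contact_map(self._ens([0.4] * 10))
        assert m.contacts[0, 1] and m.contacts[1, 0]
        assert not m.contacts[0, 0]

    def test_exact_seventy_percent_inclusive(self):
        m = occupancy_contact_map(self._ens([0.4] * 7 + [0.8] * 3))
        assert m.contacts[0, 1]
        assert m.occupancy[0, 1] == pytest.approx(0.7)

    def test_below_seventy_percent_excluded(self):
        m = occupancy_contact_map(self._ens([0.4] * 6 + [0.8] * 4))
        assert not m.contacts[0, 1]

    def test_always_beyond_cutoff(self):
        m = occupancy_contact_map(self._ens([0.55] * 10))
        assert not m.contacts[0, 1]


class TestBuildGraph:
    def _inputs(self, r01=0.5, contact=True):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = r01
        r[1, 2] = r[2, 1] = 0.9
        contacts = np.zeros((3, 3), dtype=bool)
        contacts[1, 2] = contacts[2, 1] = True
        if contact:
            contacts[0, 1] = contacts[1, 0] = True
        corr = CorrelationMatrix(r=r, mi=np.zeros((3, 3)))
        cmap = OccupancyContactMap(contacts=contacts)
        return corr, cmap

    def test_weight_is_minus_log10_r(self):
        g = build_graph(*self._inputs(r01=0.5))
        assert g[0][1]["weight"] == pytest.approx(0.30103, abs=1e-5)

    def test_perfect_correlation_zero_weight(self):
        g = build_graph(*self._inputs(r01=1.0))
        assert g[0][1]["weight"] == 0.0

    def test_contact_filter_dominates(self):
        corr, cmap = self._inputs(r01=0.99, contact=False)
        g = build_graph(corr, cmap)
        assert not g.has_edge(0, 1)

    def test_zero_correlation_edge_omitted(self):
        g = build_graph(*self._inputs(r01=0.0))
        assert not g.has_edge(0, 1)

    def test_shape_mismatch_rejected(self):
        corr, _ = self._inputs()
        cmap = OccupancyContactMap(contacts=np.zeros((4, 4), dtype=bool))
        with pytest.raises(ValueError, match="node sets"):
            build_graph(corr, cmap)


def _enumerate_shortest(graph, source, target):
    best = (np.inf, None)
    for path in nx.all_simple_paths(graph, source, target):
        w = sum(graph[a][b]["weight"] for a, b in zip(path[:-1], path[1:]))
        if w < best[0] - 1e-12 or (abs(w - best[0]) <= 1e-12 and
                                   (best[1] is None or path < best[1])):
            best = (w, list(path))
    return best


class TestShortestPaths:
    def test_triangle(self):
        g = nx.Graph()
        g.add_weighted_edges_from([(0, 1, 0.1), (1, 2, 0.1), (0, 2, 0.3)])
        p = shortest_paths(g, 0, [2])[0]
        assert p.nodes == [0, 1, 2]
        assert p.total_weight == pytest.approx(0.2)
        assert p.edge_weights == [pytest.approx(0.1), pytest.approx(0.1)]

    def test_source_equals_target(self):
        g = nx.Graph()
        g.add_weighted_edges_from([(0, 1, 0.5)])
        p = shortest_paths(g, 0, [0])[0]
        assert p.nodes == [0] and p.total_weight == 0.0

    def test_unreachable_target_reported(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1, 2])
        g.add_edge(0, 1, weight=1.0)
        p = shortest_paths(g, 0, [2])[0]
        assert not p.reachable

    def test_missing_source_is_error(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=1.0)
        with pytest.raises(ValueError, match="source"):
            shortest_paths(g, 7, [1])

    def test_matches_enumeration_on_random_graphs(self):
        """Dijkstra equals exhaustive simple-path enumeration (100 seeded
        random graphs of <= 8 nodes)."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = rng.integers(3, 9)
            g = nx.gnp_random_graph(int(n), 0.5, seed=int(rng.integers(2**31)))
            for a, b in g.edges:
                g[a][b]["weight"] = float(rng.uniform(0.01, 1.0))
            nodes = list(g.nodes)
            s, t = nodes[0], nodes[-1]
            ours = shortest_paths(g, s, [t])[0]
            w, path = _enumerate_shortest(g, s, t)
            if path is None:
                assert not ours.reachable
            else:
                assert ours.total_weight == pytest.approx(w, abs=1e-9)
                assert ours.nodes == path

    def test_lexicographic_tie_break(self):
        g = nx.Graph()
        # two equal-weight routes 0-1-3 and 0-2-3; the smaller node wins
        g.add_weighted_edges_from([(0, 1, 0.2), (1, 3, 0.2),
                                   (0, 2, 0.2), (2, 3, 0.2)])
        p = shortest_paths(g, 0, [3])[0]
        assert p.nodes == [0, 1, 3]

    def test_raising_correlation_never_lengthens_paths(self):
        """Increasing one r_MI (lowering one edge weight) can only shrink
        shortest-path totals."""
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(8, 0.6, seed=3)
        for a, b in g.edges:
            g[a][b]["weight"] = float(-np.log10(rng.uniform(0.2, 0.95)))
        before = dict(nx.all_pairs_dijkstra_path_length(g))
        edge = list(g.edges)[0]
        g[edge[0]][edge[1]]["weight"] *= 0.5
        after = dict(nx.all_pairs_dijkstra_path_length(g))
        for u in before:
            for v in before[u]:
                assert after[u][v] <= before[u][v] + 1e-12


class TestReplicaAverage:
    def _cm(self, val):
        r = np.eye(2)
        r[0, 1] = r[1, 0] = val
        return CorrelationMatrix(r=r, mi=np.zeros((2, 2)))

    def test_identical_replicas(self):
        avg = replica_average([self._cm(0.5), self._cm(0.5)])
        assert avg.r[0, 1] == 0.5

    def test_arithmetic_mean(self):
        avg = replica_average([self._cm(0.4), self._cm(0.6)])
        assert avg.r[0, 1] == pytest.approx(0.5)

    def test_identical_systems_zero_difference(self):
        d = correlation_difference([self._cm(0.4)], [self._cm(0.4)])
        np.testing.assert_allclose(d, 0.0)

    def test_node_set_mismatch(self):
        other = CorrelationMatrix(r=np.eye(3), mi=np.zeros((3, 3)))
        with pytest.raises(ValueError, match="node sets"):
            replica_average([self._cm(0.4), other])
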