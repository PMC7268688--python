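"""Graph metrics against brute-force and networkx oracles, null-model
invariants, and the small-world classification."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from volcov import (
    BrainNetwork,
    NullModelConfig,
    characteristic_path_length,
    clustering_coefficient,
    global_efficiency,
    local_efficiency,
    metrics_over_range,
    random_null_metrics,
    small_world,
)
from volcov.core_data import MetricReport, SparsityMetrics
from volcov.graph_metrics import rewire_preserving_degrees, weighted_clustering_coefficient

from conftest import random_adjacency


# --- tiny named graphs -----------------------------------------------------

def complete(n):
    return (np.ones((n, n)) - np.eye(n)).astype(int)


def path3():
    return np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])


def cycle(n):
    a = np.zeros((n, n), dtype=int)
    for i in range(n):
        a[i, (i + 1) % n] = a[(i + 1) % n, i] = 1
    return a


def k4_minus_edge():
    a = complete(4)
    a[0, 1] = a[1, 0] = 0
    return a


def star(n):
    a = np.zeros((n, n), dtype=int)
    a[0, 1:] = a[1:, 0] = 1
    return a


def two_triangles():
    a = np.zeros((6, 6), dtype=int)
    for block in (range(3), range(3, 6)):
        for i, j in itertools.combinations(block, 2):
            a[i, j] = a[j, i] = 1
    return a


# --- brute-force oracles (exhaustive enumeration / Floyd–Warshall) ---------

def brute_clustering(adj):
    n = len(adj)
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(adj[u][v] for u, v in itertools.combinations(nbrs, 2))
        cs.append(2.0 * links / (k * (k - 1)))
    return cs, sum(cs) / n


def brute_distances(adj):
    n = len(adj)
    d = [[0 if i == j else (1 if adj[i][j] else float("inf")) for j in range(n)]
         for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def brute_lp(adj):
    d = brute_distances(adj)
    finite = [v for i, row in enumerate(d) for j, v in enumerate(row)
              if i != j and v < float("inf")]
    return (sum(finite) / len(finite)) if finite else float("nan")


def brute_eglob(adj):
    n = len(adj)
    d = brute_distances(adj)
    s = sum(1.0 / d[i][j] for i in range(n) for j in range(n)
            if i != j and d[i][j] < float("inf"))
    return s / (n * (n - 1))


def brute_eloc(adj):
    n = len(adj)
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        if len(nbrs) >= 2:
            sub = [[adj[u][v] for v in nbrs] for u in nbrs]
            total += brute_eglob(sub)
    return total / n


# --- worked examples -------------------------------------------------------

class TestClustering:
    def test_triangle(self):
        per, cp = clustering_coefficient(complete(3))
        assert np.allclose(per, 1.0) and cp == 1.0

    def test_path_has_no_triangles(self):
        assert clustering_coefficient(path3())[1] == 0.0

    def test_k4_minus_edge(self):
        assert clustering_coefficient(k4_minus_edge())[1] == pytest.approx(5 / 6)

    def test_rejects_nonbinary(self):
        with pytest.raises(ValueError, match="binary"):
            clustering_coefficient(np.array([[0, 0.5], [0.5, 0]]))

    def test_weighted_form_reduces_to_binary(self, rng):
        a = random_adjacency(rng, 10)
        per_b, cp_b = clustering_coefficient(a)
        per_w, cp_w = weighted_clustering_coefficient(a.astype(float))
        assert np.allclose(per_b, per_w) and cp_b == pytest.approx(cp_w)

    def test_weighted_form_matches_networkx_onnela(self, rng):
        w = rng.uniform(0.1, 2.0, (8, 8))
        w = np.triu(w, 1)
        w = (w + w.T) * random_adjacency(rng, 8, 0.6)
        G = nx.from_numpy_array(w)
        expected = nx.clustering(G, weight="weight")
        per, _ = weighted_clustering_coefficient(w)
        assert np.allclose(per, [expected[i] for i in range(8)])


class TestPathLengthAndEfficiency:
    def test_complete_graph_lp_one(self):
        lp, disc = characteristic_path_length(complete(4))
        assert lp == 1.0 and not disc

    def test_cycle5(self):
        lp, disc = characteristic_path_length(cycle(5))
        assert lp == pytest.approx(1.5) and not disc
        assert global_efficiency(cycle(5)) == pytest.approx(0.75)
        assert local_efficiency(cycle(5)) == 0.0

    def test_disjoint_triangles_flagged(self):
        lp, disc = characteristic_path_length(two_triangles())
        assert lp == pytest.approx(1.0) and disc

    def test_edgeless_graph(self):
        lp, disc = characteristic_path_length(np.zeros((4, 4), dtype=int))
        assert np.isnan(lp) and disc
        assert global_efficiency(np.zeros((4, 4), dtype=int)) == 0.0

    def test_complete_eglob_and_eloc_one(self):
        for n in (3, 5, 8):
            assert global_efficiency(complete(n)) == pytest.approx(1.0)
        assert local_efficiency(complete(4)) == pytest.approx(1.0)

    def test_star_eloc_zero(self):
        assert local_efficiency(star(6)) == 0.0


class TestOracleEquivalence:
    def test_200_random_graphs_match_brute_force(self):
        """Cp, Lp, Eglob, Eloc equal exhaustive enumeration to 1e-10."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(4, 13))
            a = random_adjacency(rng, n, float(rng.uniform(0.15, 0.8)))
            al = a.tolist()
            assert clustering_coefficient(a)[1] == pytest.approx(
                brute_clustering(al)[1], abs=1e-10)
            lp, _ = characteristic_path_length(a)
            blp = brute_lp(al)
            assert (np.isnan(lp) and np.isnan(blp)) or lp == pytest.approx(blp, abs=1e-10)
            assert global_efficiency(a) == pytest.approx(brute_eglob(al), abs=1e-10)
            assert local_efficiency(a) == pytest.approx(brute_eloc(al), abs=1e-10)

    def test_matches_networkx_on_connected_graphs(self, rng):
        for _ in range(20):
            a = random_adjacency(rng, 12, 0.5)
            G = nx.from_numpy_array(a)
            if not nx.is_connected(G):
                continue
            assert clustering_coefficient(a)[1] == pytest.approx(nx.average_clustering(G))
            assert characteristic_path_length(a)[0] == pytest.approx(
                nx.average_shortest_path_length(G))
            assert global_efficiency(a) == pytest.approx(nx.global_efficiency(G))
            assert local_efficiency(a) == pytest.approx(nx.local_efficiency(G))


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_adding_an_edge_never_decreases_eglob(seed):
    rng = np.random.default_rng(seed)
    a = random_adjacency(rng, 10, 0.3)
    base = global_efficiency(a)
    missing = np.argwhere((a == 0) & ~np.eye(10, dtype=bool))
    if len(missing):
        i, j = missing[rng.integers(len(missing))]
        b = a.copy()
        b[i, j] = b[j, i] = 1
        assert global_efficiency(b) >= base - 1e-12


class TestNullModel:
    def test_degree_sequence_preserved(self, rng):
        a = random_adjacency(rng, 20, 0.3)
        for _ in range(10):
            b = rewire_preserving_degrees(a, rng)
            assert np.array_equal(b.sum(1), a.sum(1))
            assert np.array_equal(b, b.T)
            assert np.all(np.diag(b) == 0)

    def test_rigid_degree_sequence_returns_input_metrics(self):
        crand, lrand = random_null_metrics(complete(3), NullModelConfig(n_null=5, seed=0))
        assert crand == 1.0 and lrand == 1.0

    def test_seed_reproducibility_to_the_last_bit(self, rng):
        a = random_adjacency(rng, 30, 0.2)
        cfg = NullModelConfig(n_null=20, seed=42)
        assert random_null_metrics(a, cfg) == random_null_metrics(a, cfg)

    def test_randomization_destroys_lattice_clustering(self):
        G = nx.watts_strogatz_graph(64, 6, 0.0, seed=1)  # pure ring lattice
        a = nx.to_numpy_array(G).astype(int)
        cp = clustering_coefficient(a)[1]
        crand, _ = random_null_metrics(a, NullModelConfig(n_null=20, seed=3))
        assert crand < cp

    def test_too_few_edges_rejected(self):
        a = np.zeros((4, 4), dtype=int)
        a[0, 1] = a[1, 0] = 1
        with pytest.raises(ValueError, match="2 edges"):
            random_null_metrics(a)


class TestSmallWorld:
    def test_k3_is_not_small_world(self):
        res = small_world(complete(3), NullModelConfig(n_null=5, seed=0))
        assert res.gamma == 1.0 and res.lam == 1.0 and not res.is_small_world

    @pytest.mark.parametrize("seed", range(10))
    def test_watts_strogatz_gamma_exceeds_one(self, seed):
        G = nx.watts_strogatz_graph(64, 6, 0.1, seed=seed)
        a = nx.to_numpy_array(G).astype(int)
        res = small_world(a, NullModelConfig(n_null=20, seed=seed))
        assert res.gamma > 1

    def test_erdos_renyi_gamma_near_one(self):
        gammas = []
        for seed in range(10):
            G = nx.gnm_random_graph(64, 192, seed=seed)
            a = nx.to_numpy_array(G).astype(int)
            gammas.append(small_world(a, NullModelConfig(n_null=20, seed=seed)).gamma)
        assert abs(np.median(gammas) - 1) < 0.15  # ER is its own null family


class TestMetricsOverRange:
    def test_constant_metric_auc_rectangle(self):
        per = {s: SparsityMetrics(cp=2.0, lp=2.0, eglob=2.0, eloc=2.0)
               for s in np.round(np.arange(0.1, 0.51, 0.02), 2)}
        net_like = MetricReport(per_sparsity=per)
        # rectangle rule via the real aggregation path
        xs = sorted(per)
        assert np.trapezoid([per[s].cp for s in xs], xs) == pytest.approx(0.8)

    def test_report_shape_and_auc(self, small_cohort):
        from volcov import build_network

        net = build_network(small_cohort["BET"], sparsity_range=(0.1, 0.2, 0.3))
        report = metrics_over_range(net, NullModelConfig(n_null=4, seed=0))
        assert report.sparsities == [0.1, 0.2, 0.3]
        for s in report.sparsities:
            m = report.per_sparsity[s]
            assert 0 <= m.cp <= 1 and 0 <= m.eglob <= 1 and 0 <= m.eloc <= 1
            assert m.lp >= 1
            assert m.gamma is not None and m.gamma > 0
        assert set(report.auc) >= {"cp", "lp", "eglob", "eloc"}

    def test_single_sparsity_level_no_auc(self, small_cohort):
        from volcov import build_network

        net = build_network(small_cohort["BET"], sparsity_range=(0.2,))
        report = metrics_over_range(net, NullModelConfig(n_null=0))
        assert report.auc == {}
        assert report.per_sparsity[0.2].cp >= 0
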