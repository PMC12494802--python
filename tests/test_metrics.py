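import numpy as np
import pytest
from scipy.spatial.distance import cdist

from grnembed.gae import decode_edges
from grnembed.metrics import (
    average_precision,
    centrality_correlations,
    divergence_report,
    jensen_shannon_distance,
    kl_per_dimension,
    kmeans_labels,
    mmd_rbf,
    neighborhood_preservation,
    pca_2d,
    regulation_type_scores,
    roc_auc,
    silhouette,
    wasserstein_mean,
)
from grnembed.regnet_io import Regulation, RegulatoryInteraction, build_graph
from grnembed.synthetic_data import GaussianSampleConfig, generate_gaussian_embeddings


# ------------------------------------------------------------------- oracles

def auc_pair_counting(pos, neg):
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def silhouette_bruteforce(x, labels):
    n = len(x)
    d = cdist(x, x)
    vals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([d[i, j] for j in same])
        b = min(
            np.mean([d[i, j] for j in range(n) if labels[j] == lab])
            for lab in set(labels) if lab != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def np_bruteforce(graph, x, k):
    d = cdist(x, x)
    fracs = []
    for i in range(len(x)):
        nbrs = {t for s, t in graph.edges if s == i} | {
            s for s, t in graph.edges if t == i}
        nbrs.discard(i)
        if not nbrs:
            continue
        others = sorted(range(len(x)), key=lambda j: (d[i, j], j))
        others = [j for j in others if j != i][:k]
        fracs.append(len(set(others) & nbrs) / k)
    return float(np.mean(fracs))


def mmd_double_loop(x, y, sigma):
    def k(a, b):
        return np.exp(-np.sum((a - b) ** 2) / (2 * sigma**2))
    kxx = np.mean([[k(a, b) for b in x] for a in x])
    kyy = np.mean([[k(a, b) for b in y] for a in y])
    kxy = np.mean([[k(a, b) for b in y] for a in x])
    return kxx + kyy - 2 * kxy


# --------------------------------------------------------------------- tests

class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8], [0.2, 0.1]) == 1.0

    def test_all_tied_half(self):
        assert roc_auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_spec_example(self):
        assert roc_auc([0.9, 0.4], [0.5, 0.1]) == pytest.approx(0.75)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [0.1])

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(200):
            n_pos = rng.integers(1, 20)
            n_neg = rng.integers(1, 20)
            # quantized scores to force ties
            pos = rng.integers(0, 6, n_pos) / 5.0
            neg = rng.integers(0, 6, n_neg) / 5.0
            assert roc_auc(pos, neg) == pytest.approx(
                auc_pair_counting(pos, neg), abs=1e-12)


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert average_precision([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_single_positive_ranked_second(self):
        assert average_precision([0.9, 0.4], [0, 1]) == pytest.approx(0.5)

    def test_bounded(self, rng):
        for _ in range(50):
            s = rng.random(20)
            y = (rng.random(20) < 0.3).astype(int)
            if y.sum() == 0:
                continue
            ap = average_precision(s, y)
            assert 0.0 <= ap <= 1.0

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            average_precision([0.5], [0])


class TestSilhouette:
    def test_two_tight_far_clusters(self, rng):
        a = rng.normal(scale=0.01, size=(30, 3))
        b = rng.normal(scale=0.01, size=(30, 3)) + 100.0
        x = np.vstack([a, b])
        labels = np.array([0] * 30 + [1] * 30)
        assert silhouette(x, labels) > 0.9

    def test_random_labels_near_zero(self, rng):
        x = rng.normal(size=(500, 4))
        labels = rng.integers(0, 3, 500)
        assert abs(silhouette(x, labels)) < 0.05

    def test_matches_bruteforce(self, rng):
        x = rng.normal(size=(50, 3))
        labels = rng.integers(0, 3, 50)
        assert silhouette(x, labels) == pytest.approx(
            silhouette_bruteforce(x, labels), abs=1e-10)

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            silhouette(rng.normal(size=(10, 2)), np.zeros(10))


class TestKMeans:
    def test_determinism(self, rng):
        x = rng.normal(size=(60, 4))
        assert np.array_equal(kmeans_labels(x, 3, seed=1),
                              kmeans_labels(x, 3, seed=1))

    def test_k_equals_distinct_points_zero_inertia(self):
        x = np.array([[0.0, 0.0], [5.0, 5.0], [9.0, 0.0]])
        labels = kmeans_labels(x, 3, seed=0)
        assert len(set(labels.tolist())) == 3

    def test_recovers_separated_blobs(self, rng):
        from sklearn.metrics import adjusted_rand_score
        centers = np.array([[0, 0], [10, 0], [0, 10]], dtype=float)
        truth = rng.integers(0, 3, 300)
        x = centers[truth] + rng.normal(scale=1.0, size=(300, 2))
        labels = kmeans_labels(x, 3, seed=0)
        assert adjusted_rand_score(truth, labels) > 0.95

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_labels(rng.normal(size=(3, 2)), 5)


class TestNeighborhoodPreservation:
    def test_engineered_perfect_score(self):
        # 6-node cycle (undirected degree 2), k=2, coordinates on a circle:
        # each node's two graph neighbors are its two nearest points
        rows = [RegulatoryInteraction(f"N{i}", f"N{(i+1) % 6}", Regulation.UNKNOWN)
                for i in range(6)]
        graph = build_graph(rows)
        theta = np.array([2 * np.pi * i / 6 for i in range(6)])
        coords = np.stack([np.cos(theta), np.sin(theta)], axis=1)
        x = np.zeros_like(coords)
        for i in range(6):
            x[graph.node_index[f"N{i}"]] = coords[i]
        assert neighborhood_preservation(graph, x, k=2) == pytest.approx(1.0)

    def test_random_embeddings_hypergeometric_expectation(self, rng):
        from grnembed.synthetic_data import NetworkGenConfig, generate_network
        cfg = NetworkGenConfig(seed=13)
        graph = build_graph(generate_network(cfg))
        k, n = 5, graph.n_nodes
        trials = [
            neighborhood_preservation(graph, rng.normal(size=(n, 8)), k=k)
            for _ in range(10)
        ]
        deg = np.zeros(n)
        for s, t in graph.edges:
            if s != t:
                deg[s] += 1
                deg[t] += 1
        # per eligible node, expected overlap fraction is deg/(n-1)
        expected = float(np.mean([d / (n - 1) for d in deg if d > 0]))
        assert np.mean(trials) == pytest.approx(expected, abs=0.01)

    def test_matches_bruteforce(self, rng):
        from grnembed.synthetic_data import NetworkGenConfig, generate_network
        cfg = NetworkGenConfig(n_tf=8, n_target=20, n_overlap=3, n_rows=60,
                               duplicate_fraction=0.1, seed=9)
        graph = build_graph(generate_network(cfg))
        assert graph.n_nodes <= 30
        x = rng.normal(size=(graph.n_nodes, 4))
        assert neighborhood_preservation(graph, x, k=4) == pytest.approx(
            np_bruteforce(graph, x, 4), abs=1e-12)

    def test_k_too_large_rejected(self, small_graph, rng):
        with pytest.raises(ValueError):
            neighborhood_preservation(
                small_graph, rng.normal(size=(small_graph.n_nodes, 2)),
                k=small_graph.n_nodes)


class TestCentralityCorrelations:
    def test_norms_proportional_to_degree(self, small_graph):
        deg = np.zeros(small_graph.n_nodes)
        for s, t in small_graph.edges:
            if s != t:
                deg[s] += 1
                deg[t] += 1
        x = np.zeros((small_graph.n_nodes, 2))
        x[:, 0] = deg  # norm == degree exactly
        table = centrality_correlations(small_graph, x)
        assert table["degree"]["pearson"] == pytest.approx(1.0)
        assert table["degree"]["spearman"] == pytest.approx(1.0)

    def test_star_graph_center_dominates(self):
        rows = [RegulatoryInteraction("HUB", f"L{i}", Regulation.UNKNOWN)
                for i in range(8)]
        graph = build_graph(rows)
        import networkx as nx
        g = nx.Graph()
        g.add_edges_from(graph.edges)
        bc = nx.betweenness_centrality(g)
        hub = graph.node_index["HUB"]
        assert g.degree(hub) == max(dict(g.degree).values())
        assert bc[hub] == max(bc.values())

    def test_spearman_invariant_under_monotone_transform(self, small_graph, rng):
        x = rng.uniform(0.5, 2.0, size=(small_graph.n_nodes, 3))
        t1 = centrality_correlations(small_graph, x)
        # cubing norms preserves their ranks
        norms = np.linalg.norm(x, axis=1)
        x2 = x * ((norms**3 / norms)[:, None])
        t2 = centrality_correlations(small_graph, x2)
        for measure in t1:
            assert t1[measure]["spearman"] == pytest.approx(
                t2[measure]["spearman"], abs=1e-12)

    def test_constant_norms_reported_missing(self, small_graph):
        x = np.ones((small_graph.n_nodes, 4))
        table = centrality_correlations(small_graph, x)
        assert table["degree"]["pearson"] is None


class TestKL:
    def test_identical_samples_zero(self, rng):
        x = rng.normal(size=(500, 4))
        fwd, rev, sym, flagged = kl_per_dimension(x, x.copy())
        assert np.allclose(fwd, 0.0, atol=1e-9)
        assert np.allclose(rev, 0.0, atol=1e-9)
        assert not flagged

    def test_nonnegative(self, rng):
        x = rng.normal(size=(400, 5))
        y = rng.normal(loc=0.5, size=(400, 5))
        fwd, rev, sym, _ = kl_per_dimension(x, y)
        assert np.all(fwd >= 0) and np.all(rev >= 0) and np.all(sym >= 0)

    def test_gaussian_closed_form(self):
        x = generate_gaussian_embeddings(GaussianSampleConfig(n=50_000, d=1,
                                                              mean=1.0, seed=1))
        y = generate_gaussian_embeddings(GaussianSampleConfig(n=50_000, d=1,
                                                              mean=0.0, seed=2))
        fwd, _, _, _ = kl_per_dimension(x, y)
        assert abs(fwd[0] - 0.5) < 0.075  # within 15% of KL(N(1,1)||N(0,1)) = 0.5

    def test_estimator_consistency_in_n(self):
        errs = []
        for n in (1_000, 100_000):
            x = generate_gaussian_embeddings(
                GaussianSampleConfig(n=n, d=1, mean=1.0, seed=3))
            y = generate_gaussian_embeddings(
                GaussianSampleConfig(n=n, d=1, mean=0.0, seed=4))
            fwd, _, _, _ = kl_per_dimension(x, y)
            errs.append(abs(fwd[0] - 0.5))
        assert errs[1] < errs[0]

    def test_degenerate_dimension_flagged(self):
        x = np.zeros((50, 2))
        y = np.zeros((50, 2))
        x[:, 0] = np.linspace(0, 1, 50)
        y[:, 0] = np.linspace(0, 1, 50)
        fwd, rev, sym, flagged = kl_per_dimension(x, y)
        assert flagged == [1]
        assert fwd[1] == 0.0


class TestJensenShannon:
    def test_identical_zero(self, rng):
        x = rng.normal(size=(300, 3))
        assert jensen_shannon_distance(x, x.copy()) == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_supports_sqrt_ln2(self, rng):
        x = rng.uniform(0, 1, size=(2000, 2))
        y = rng.uniform(10, 11, size=(2000, 2))
        assert jensen_shannon_distance(x, y) == pytest.approx(
            np.sqrt(np.log(2)), rel=0.01)

    def test_symmetry(self, rng):
        x = rng.normal(size=(200, 3))
        y = rng.normal(loc=1.0, size=(200, 3))
        assert jensen_shannon_distance(x, y) == pytest.approx(
            jensen_shannon_distance(y, x), abs=1e-12)


class TestWasserstein:
    def test_identical_zero(self, rng):
        x = rng.normal(size=(100, 2))
        assert wasserstein_mean(x, x.copy()) == 0.0

    def test_point_masses(self):
        x = np.full((20, 1), 3.0)
        y = np.full((30, 1), -1.5)
        assert wasserstein_mean(x, y) == pytest.approx(4.5)

    def test_gaussian_location_shift(self):
        x = generate_gaussian_embeddings(GaussianSampleConfig(n=30_000, d=2,
                                                              mean=2.0, seed=5))
        y = generate_gaussian_embeddings(GaussianSampleConfig(n=30_000, d=2,
                                                              mean=0.0, seed=6))
        assert wasserstein_mean(x, y) == pytest.approx(2.0, rel=0.02)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wasserstein_mean(np.zeros((0, 1)), np.zeros((5, 1)))


class TestMMD:
    def test_identical_zero(self, rng):
        x = rng.normal(size=(50, 4))
        for v in mmd_rbf(x, x.copy()).values():
            assert abs(v) < 1e-12

    def test_single_point_closed_form(self):
        sigma = 0.7
        x = np.zeros((1, 2))
        y = np.array([[np.sqrt(2) * sigma, 0.0]])  # ||x-y||^2 = 2 sigma^2
        val = mmd_rbf(x, y, sigmas=[sigma])[sigma]
        assert val == pytest.approx(2 * (1 - np.exp(-1)), abs=1e-12)

    def test_large_sigma_vanishes(self, rng):
        x = rng.normal(size=(40, 3))
        y = rng.normal(loc=2.0, size=(40, 3))
        assert mmd_rbf(x, y, sigmas=[1e6])[1e6] == pytest.approx(0.0, abs=1e-6)

    def test_matches_double_loop_oracle(self, rng):
        x = rng.normal(size=(15, 3))
        y = rng.normal(loc=0.5, size=(12, 3))
        for sigma in (0.5, 1.0, 2.0):
            assert mmd_rbf(x, y, sigmas=[sigma])[sigma] == pytest.approx(
                mmd_double_loop(x, y, sigma), abs=1e-12)

    def test_nonpositive_sigma_rejected(self, rng):
        with pytest.raises(ValueError):
            mmd_rbf(rng.normal(size=(5, 2)), rng.normal(size=(5, 2)), sigmas=[0.0])


class TestRegulationTypeScores:
    def test_zero_embeddings_half_scores(self):
        rows = [
            RegulatoryInteraction("A", "B", Regulation.ACTIVATION),
            RegulatoryInteraction("A", "C", Regulation.REPRESSION),
            RegulatoryInteraction("A", "B", Regulation.ACTIVATION),
        ]
        graph = build_graph(rows)
        z = np.zeros((graph.n_nodes, 4))
        out = regulation_type_scores(rows, graph, {"GAE": z})
        assert out["Activation"]["count"] == 2
        assert out["Repression"]["count"] == 1
        assert out["Activation"]["GAE_mean"] == pytest.approx(0.5)
        assert out["Activation"]["GAE_std"] == pytest.approx(0.0)

    def test_counts_sum_to_rows(self, small_net_config, small_graph, rng):
        from grnembed.synthetic_data import generate_network
        rows = generate_network(small_net_config)
        z = rng.normal(size=(small_graph.n_nodes, 8))
        out = regulation_type_scores(rows, small_graph, {"GAE": z})
        assert sum(v["count"] for v in out.values()) == len(rows)

    def test_unknown_symbol_rejected(self, rng):
        rows = [RegulatoryInteraction("A", "B", Regulation.UNKNOWN)]
        graph = build_graph(rows)
        stranger = [RegulatoryInteraction("A", "Z", Regulation.UNKNOWN)]
        with pytest.raises(KeyError):
            regulation_type_scores(stranger, graph,
                                   {"GAE": rng.normal(size=(2, 4))})

    def test_gae_group_stds_tight_on_trained_model(self, trained_gae,
                                                   small_net_config):
        from grnembed.synthetic_data import NetworkGenConfig, generate_network
        rows = generate_network(NetworkGenConfig(seed=5))
        out = regulation_type_scores(rows, trained_gae["graph"],
                                     {"GAE": trained_gae["z"]})
        for entry in out.values():
            assert entry["GAE_std"] < 0.2


class TestPCA:
    def test_collinear_points_second_component_zero(self):
        t = np.linspace(0, 1, 30)
        x = np.stack([t, 2 * t, -t], axis=1)
        _, explained = pca_2d(x)
        assert explained[0] == pytest.approx(1.0)
        assert explained[1] == pytest.approx(0.0, abs=1e-12)

    def test_explained_variance_descending_and_bounded(self, rng):
        _, explained = pca_2d(rng.normal(size=(40, 6)))
        assert explained[0] >= explained[1] >= 0
        assert explained.sum() <= 1.0 + 1e-12

    def test_matches_eigendecomposition_oracle(self, rng):
        x = rng.normal(size=(20, 5))
        coords, explained = pca_2d(x)
        centered = x - x.mean(axis=0)
        cov = centered.T @ centered / len(x)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for i in range(2):
            v = evecs[:, i]
            proj = centered @ v
            # component defined up to sign
            assert (np.allclose(coords[:, i], proj, atol=1e-8)
                    or np.allclose(coords[:, i], -proj, atol=1e-8))
            assert explained[i] == pytest.approx(evals[i] / evals.sum())


class TestDivergenceReport:
    def test_schema_and_invariants(self, rng):
        x = rng.normal(size=(150, 6))
        y = rng.normal(loc=1.0, scale=2.0, size=(150, 6))
        rep = divergence_report(x, y)
        assert rep.kl_forward_mean >= 0
        assert rep.kl_symmetric_mean == pytest.approx(
            (rep.kl_forward_mean + rep.kl_reverse_mean) / 2)
        assert 0 <= rep.jensen_shannon_distance <= np.sqrt(np.log(2)) + 1e-9
        assert rep.wasserstein_mean >= 0
        assert all(v >= -1e-12 for v in rep.mmd.values())
        d = rep.to_dict()
        assert d["log_base"] == "nat"
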