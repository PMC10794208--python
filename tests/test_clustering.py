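import math

import numpy as np
import pytest

import contrabin as cb
from contrabin.io_formats import BinAssignment, SCGTable


class TestKnnGraph:
    def test_three_points_on_a_line(self):
        emb = np.array([[0.0], [1.0], [3.0]])
        g = cb.knn_graph(emb, k=1)
        assert {tuple(e) for e in g.edges} == {(0, 1), (1, 2)}
        # squared L2 distances
        d = dict(zip(map(tuple, g.edges), g.distances))
        assert d[(0, 1)] == pytest.approx(1.0)
        assert d[(1, 2)] == pytest.approx(4.0)

    def test_no_self_loops(self):
        rng = np.random.default_rng(0)
        g = cb.knn_graph(rng.standard_normal((30, 4)), k=5)
        assert np.all(g.edges[:, 0] != g.edges[:, 1])

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError):
            cb.knn_graph(np.zeros((3, 2)), k=3)

    def test_recovers_brute_force_neighbors(self):
        """Union of directed k-NN lists vs exhaustive distance sort."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((300, 8))
        k = 10
        g = cb.knn_graph(X, k=k)
        got = {tuple(e) for e in g.edges}
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        want = set()
        for i in range(300):
            for j in np.argsort(d2[i])[:k]:
                want.add((min(i, j), max(i, int(j))))
        recall = len(got & want) / len(want)
        assert recall >= 0.99


class TestFilterEdges:
    def graph(self, dists):
        n = len(dists) + 1
        edges = np.array([(i, i + 1) for i in range(len(dists))])
        return cb.clustering.SimilarityGraph(n_nodes=n, edges=edges,
                                             distances=np.asarray(dists, float))

    def test_ratio_one_is_identity(self):
        g = self.graph([3.0, 1.0, 2.0])
        f = cb.filter_edges(g, 1.0)
        np.testing.assert_array_equal(f.edges, g.edges)

    def test_half_keeps_smallest(self):
        g = self.graph(list(range(10, 0, -1)))
        f = cb.filter_edges(g, 0.5)
        assert len(f.distances) == 5
        assert set(f.distances) == {1, 2, 3, 4, 5}

    def test_retained_max_below_dropped_min(self):
        rng = np.random.default_rng(2)
        g = self.graph(rng.random(37))
        f = cb.filter_edges(g, 0.4)
        dropped = set(map(tuple, g.edges)) - set(map(tuple, f.edges))
        d = dict(zip(map(tuple, g.edges), g.distances))
        assert max(f.distances) <= min(d[e] for e in dropped)


class TestSimilarity:
    def test_closed_forms(self):
        g = cb.clustering.SimilarityGraph(
            n_nodes=3, edges=np.array([[0, 1], [1, 2]]),
            distances=np.array([0.0, 0.2]))
        s = cb.to_similarity(g, sigma=0.2)
        assert s.similarities[0] == pytest.approx(1.0)
        assert s.similarities[1] == pytest.approx(math.exp(-1))

    def test_monotone_decreasing_and_bounded(self):
        d = np.linspace(0, 10, 50)
        g = cb.clustering.SimilarityGraph(
            n_nodes=51, edges=np.array([(i, i + 1) for i in range(50)]),
            distances=d)
        s = cb.to_similarity(g, sigma=0.1).similarities
        assert np.all(np.diff(s) < 0)
        assert np.all((s > 0) & (s <= 1))


class TestPickSeedMarker:
    def test_most_distinct_contigs(self):
        scg = SCGTable(hits=[(f"c{i}", "m1") for i in range(5)]
                       + [(f"c{i}", "m2") for i in range(3)])
        assert cb.pick_seed_marker(scg) == "m1"

    def test_tie_breaks_lexicographically(self):
        scg = SCGTable(hits=[("c1", "m2"), ("c2", "m2"), ("c1", "m1"), ("c2", "m1")])
        assert cb.pick_seed_marker(scg) == "m1"

    def test_duplicate_hits_count_once(self):
        scg = SCGTable(hits=[("c1", "m1"), ("c1", "m1"), ("c1", "m1"),
                             ("c1", "m2"), ("c2", "m2")])
        assert cb.pick_seed_marker(scg) == "m2"

    def test_empty_table(self):
        assert cb.pick_seed_marker(SCGTable(hits=[])) is None


def two_clique_graph():
    """Two 5-node cliques with no connecting edge."""
    edges, dists = [], []
    for base in (0, 5):
        for i in range(5):
            for j in range(i + 1, 5):
                edges.append((base + i, base + j))
                dists.append(0.01)
    g = cb.clustering.SimilarityGraph(n_nodes=10, edges=np.array(edges),
                                      distances=np.array(dists))
    return cb.to_similarity(g, sigma=0.1)


class TestLeidenCluster:
    def test_two_cliques_two_bins(self):
        asg = cb.leiden_cluster(two_clique_graph(), resolution=1.0,
                                contig_lengths=[2000] * 10, seed=0)
        labels = [asg.labels[i] for i in range(10)]
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_fixed_contigs_never_merge(self):
        asg = cb.leiden_cluster(two_clique_graph(), resolution=0.001,
                                contig_lengths=[2000] * 10,
                                fixed_nodes=[0, 1], seed=0)
        assert asg.labels[0] != asg.labels[1]

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((80, 4))
        g = cb.to_similarity(cb.knn_graph(X, 10), sigma=0.3)
        a = cb.leiden_cluster(g, 5.0, [1500] * 80, seed=9)
        b = cb.leiden_cluster(g, 5.0, [1500] * 80, seed=9)
        assert a.labels == b.labels

    def test_similarity_required(self):
        g = cb.clustering.SimilarityGraph(n_nodes=2,
                                          edges=np.array([[0, 1]]),
                                          distances=np.array([1.0]))
        with pytest.raises(ValueError):
            cb.leiden_cluster(g, 1.0, [1000, 1000], seed=0)


class TestEstimateQuality:
    def scg10(self, hits):
        return SCGTable(hits=hits,
                        marker_universe={f"m{i}" for i in range(10)})

    def test_perfect_bin(self):
        asg = BinAssignment(labels={f"c{i}": 0 for i in range(10)})
        scg = self.scg10([(f"c{i}", f"m{i}") for i in range(10)])
        est = cb.estimate_quality(asg, scg, None)
        assert est.per_bin[0] == (100.0, 0.0)
        assert est.score == 6

    def test_half_complete_with_duplicate(self):
        """5 of 10 markers present, one duplicated -> (50%, 10%)."""
        hits = [("c0", f"m{i}") for i in range(5)] + [("c1", "m0")]
        asg = BinAssignment(labels={"c0": 0, "c1": 0})
        est = cb.estimate_quality(asg, self.scg10(hits), None)
        assert est.per_bin[0] == (50.0, 10.0)
        assert est.score == 0  # completeness must *exceed* 50

    def test_relabel_invariance(self):
        hits = [(f"c{i}", f"m{i}") for i in range(10)]
        a = BinAssignment(labels={f"c{i}": 0 for i in range(10)})
        b = BinAssignment(labels={f"c{i}": 42 for i in range(10)})
        ea = cb.estimate_quality(a, self.scg10(hits), None)
        eb = cb.estimate_quality(b, self.scg10(hits), None)
        assert ea.score == eb.score
        assert sorted(ea.per_bin.values()) == sorted(eb.per_bin.values())

    def test_empty_universe_warns_zero(self):
        asg = BinAssignment(labels={"c0": 0})
        est = cb.estimate_quality(asg, SCGTable(hits=[]), None)
        assert est.score == 0 and not est.per_bin

    def test_strict_thresholds(self):
        # completeness exactly 90 does not pass >90; contamination exactly 5
        # does not pass <5
        hits = [("c0", f"m{i}") for i in range(9)]
        asg = BinAssignment(labels={"c0": 0})
        est = cb.estimate_quality(asg, self.scg10(hits), None)
        assert est.six_metrics[(5, 90)] == 0
        assert est.six_metrics[(5, 70)] == 1


class TestSweep:
    def embeddings(self):
        rng = np.random.default_rng(3)
        centers = np.array([[0, 0], [6, 0], [0, 6]])
        labels = np.repeat(np.arange(3), 20)
        return centers[labels] + 0.3 * rng.standard_normal((60, 2)), labels

    def scg_for(self, labels):
        # every member carries one marker: splitting a cluster costs
        # completeness, merging two costs contamination
        hits = []
        for g in range(3):
            members = np.flatnonzero(labels == g)
            for m, node in enumerate(members):
                hits.append((f"c{node}", f"m{m:02d}"))
        return SCGTable(hits=hits,
                        marker_universe={f"m{m:02d}" for m in range(20)})

    def test_single_combination_returned(self):
        X, labels = self.embeddings()
        grid = cb.SweepGrid(sigmas=(0.3,), resolutions=(1.0,), edge_ratios=(1.0,))
        asg = cb.run_sweep_and_select(X, self.scg_for(labels),
                                      [f"c{i}" for i in range(60)],
                                      [2000] * 60, grid=grid, knn_k=8, seed=0)
        assert asg.params == (0.3, 1.0, 1.0)

    def test_selection_recovers_planted_clusters(self):
        X, labels = self.embeddings()
        asg = cb.run_sweep_and_select(X, self.scg_for(labels),
                                      [f"c{i}" for i in range(60)],
                                      [2000] * 60, knn_k=8, seed=0)
        from sklearn.metrics import adjusted_rand_score
        pred = [asg.labels[i] for i in range(60)]
        assert adjusted_rand_score(labels, pred) > 0.9

    def test_no_scg_returns_first_combination(self, caplog):
        X, _ = self.embeddings()
        grid = cb.SweepGrid(sigmas=(0.1, 0.3), resolutions=(1.0, 5.0),
                            edge_ratios=(0.5, 1.0))
        asg = cb.run_sweep_and_select(X, SCGTable(hits=[]),
                                      [f"c{i}" for i in range(60)],
                                      [2000] * 60, grid=grid, knn_k=8, seed=0)
        assert asg.params == (0.1, 1.0, 0.5)

    def test_argmax_reproducible_on_cached_partitions(self):
        parts = [BinAssignment(labels={"c": i}) for i in range(5)]
        scores = [2, 7, 7, 1, 0]
        pick1 = cb.select_best(parts, scores)
        pick2 = cb.select_best(parts, scores)
        assert pick1 is parts[1] and pick2 is parts[1]


class TestFilterSmallBins:
    def test_threshold_application(self):
        lengths = {0: 150_000, 1: 250_000}
        asg = BinAssignment(labels={0: 0, 1: 1})
        out = cb.filter_small_bins(asg, lengths)
        assert set(out.labels.values()) == {1}

    def test_exactly_200kbp_retained(self):
        asg = BinAssignment(labels={0: 0})
        out = cb.filter_small_bins(asg, {0: 200_000})
        assert out.labels == {0: 0}
        out2 = cb.filter_small_bins(asg, {0: 199_999})
        assert out2.labels == {}

    def test_empty_assignment(self):
        out = cb.filter_small_bins(BinAssignment(labels={}), {})
        assert out.labels == {}
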