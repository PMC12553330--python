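import numpy as np
import pytest
import dendropy
from sklearn.base import clone

from clonaltraj.clustering import (
    ClonalClusterer,
    call_clonal_clusters,
    cut,
    linkage,
    quantify_thresholds,
    select_threshold,
)
from clonaltraj.core import FrequencyMatrix
from clonaltraj.distance import TrajectoryDistanceMatrix, build_distance_matrix, transform_trajectories


def naive_upgma_heights(d):
    """O(n^3) average-linkage reference: returns sorted merge heights."""
    n = d.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                pair_mean = np.mean(
                    [d[i, j] for i in clusters[a] for j in clusters[b]]
                )
                if pair_mean < best[0]:
                    best = (pair_mean, (a, b))
        h, (a, b) = best
        heights.append(h)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return sorted(heights)


def random_dm(rng, n):
    m = rng.random((n, n)) * 2
    d = (m + m.T) / 2
    np.fill_diagonal(d, 0)
    ids = [f"L{i}" for i in range(n)]
    return TrajectoryDistanceMatrix(ids, d, "pearson", "linear")


def three_leaf_dm():
    d = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
    return TrajectoryDistanceMatrix(["A", "B", "C"], d, "pearson", "linear")


class TestLinkage:
    def test_hand_executed_three_leaf_upgma(self):
        tree = linkage(three_leaf_dm(), "upgma")
        assert np.allclose(sorted(tree.merges[:, 2]), [1.0, 4.0])

    def test_two_leaves_merge_at_their_distance(self):
        dm = TrajectoryDistanceMatrix(
            ["A", "B"], np.array([[0.0, 0.7], [0.7, 0.0]]), "pearson", "linear"
        )
        tree = linkage(dm)
        assert tree.merges.shape == (1, 4)
        assert tree.merges[0, 2] == pytest.approx(0.7)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_average_linkage(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        dm = random_dm(rng, n)
        tree = linkage(dm, "upgma")
        assert np.allclose(
            sorted(tree.merges[:, 2]), naive_upgma_heights(dm.d), atol=1e-12
        )

    def test_upgma_heights_monotone(self):
        rng = np.random.default_rng(42)
        tree = linkage(random_dm(rng, 12))
        assert np.all(np.diff(tree.merges[:, 2]) >= -1e-12)

    def test_upgmc_requires_trajectories(self):
        with pytest.raises(ValueError, match="trajectory"):
            linkage(three_leaf_dm(), "upgmc")

    def test_upgmc_on_trajectories(self):
        rng = np.random.default_rng(1)
        T = rng.normal(size=(6, 5))
        dm = random_dm(rng, 6)
        tree = linkage(dm, "upgmc", trajectories=T)
        assert tree.method == "upgmc"
        assert tree.merges.shape == (5, 4)

    def test_nan_rejected(self):
        dm = three_leaf_dm()
        d = dm.d.copy(); d[0, 1] = d[1, 0] = np.nan
        bad = TrajectoryDistanceMatrix(dm.ids, d, "pearson", "linear")
        with pytest.raises(ValueError, match="NaN"):
            linkage(bad)


class TestCut:
    def test_extreme_heights(self):
        tree = linkage(three_leaf_dm())
        assert len(set(cut(tree, 0.0).values())) == 3
        assert len(set(cut(tree, 10.0).values())) == 1

    def test_intermediate_height(self):
        labels = cut(linkage(three_leaf_dm()), 2.0)
        assert labels["A"] == labels["B"] != labels["C"]

    def test_labels_ordered_by_smallest_member(self):
        labels = cut(linkage(three_leaf_dm()), 2.0)
        assert labels["A"] == 0 and labels["C"] == 1

    def test_lower_cuts_refine_higher_cuts(self):
        rng = np.random.default_rng(5)
        tree = linkage(random_dm(rng, 10))
        lo = cut(tree, 0.3)
        hi = cut(tree, 0.9)
        # each low-height cluster maps into exactly one high-height cluster
        mapping = {}
        for b in lo:
            mapping.setdefault(lo[b], set()).add(hi[b])
        assert all(len(v) == 1 for v in mapping.values())


class TestNewick:
    def test_newick_depths_match_merge_heights(self):
        tree = linkage(three_leaf_dm())
        t = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        depths = {
            leaf.taxon.label: leaf.distance_from_root() for leaf in t.leaf_node_iter()
        }
        assert set(depths) == {"A", "B", "C"}
        assert all(abs(v - 4.0) < 1e-9 for v in depths.values())


class TestQuantify:
    def test_grid_endpoints(self):
        rng = np.random.default_rng(2)
        dm = random_dm(rng, 7)
        T = rng.normal(size=(7, 5))
        tree = linkage(dm)
        q = quantify_thresholds(tree, dm, T, grid_size=10)
        assert q.n_clusters[0] == 7
        assert q.n_clusters[-1] == 1
        assert np.all(np.diff(q.n_clusters) <= 0)
        assert np.isnan(q.centroid_separation[-1])

    def test_grid_size_two_gives_endpoints_only(self):
        rng = np.random.default_rng(3)
        dm = random_dm(rng, 5)
        tree = linkage(dm)
        q = quantify_thresholds(tree, dm, rng.normal(size=(5, 4)), grid_size=2)
        assert len(q.thresholds) == 2
        assert q.thresholds[0] == 0.0
        assert q.thresholds[-1] == pytest.approx(tree.max_height)

    def test_two_family_plateau(self):
        # two tight trajectory families -> plateau at n_clusters == 2 spanning
        # the gap between within- and between-family merge heights
        rng = np.random.default_rng(8)
        base1 = np.linspace(-1, -3, 6)
        base2 = np.linspace(-3, -1, 6)
        T = np.vstack(
            [base1 + rng.normal(0, 0.01, 6) for _ in range(5)]
            + [base2 + rng.normal(0, 0.01, 6) for _ in range(5)]
        )
        ids = [f"b{i}" for i in range(10)]
        fm = FrequencyMatrix(ids, np.arange(6.0), 10.0**T, 1e-6, filtered=True)
        dm = build_distance_matrix(fm, "pearson", "log10_floored")
        tree = linkage(dm)
        q = quantify_thresholds(tree, dm, T, grid_size=100)
        within = tree.merges[:-1, 2].max()
        between = tree.merges[-1, 2]
        in_gap = (q.thresholds > within) & (q.thresholds < between)
        assert in_gap.sum() > 50  # wide plateau
        assert np.all(q.n_clusters[in_gap] == 2)
        # and the plateau rule lands inside it
        h = select_threshold(q, "plateau")
        assert within < h < between

    def test_knee_rule_returns_grid_point(self):
        rng = np.random.default_rng(4)
        dm = random_dm(rng, 9)
        tree = linkage(dm)
        q = quantify_thresholds(tree, dm, rng.normal(size=(9, 5)), 50)
        h = select_threshold(q, "knee")
        assert h in q.thresholds

    def test_unknown_rule_rejected(self):
        rng = np.random.default_rng(4)
        dm = random_dm(rng, 4)
        tree = linkage(dm)
        q = quantify_thresholds(tree, dm, rng.normal(size=(4, 5)), 10)
        with pytest.raises(ValueError):
            select_threshold(q, "magic")


def two_family_freqs():
    rng = np.random.default_rng(6)
    rising = np.linspace(0.01, 0.2, 5)
    falling = np.linspace(0.2, 0.01, 5)
    rows = [rising * rng.uniform(0.8, 1.2) for _ in range(3)]
    rows += [falling * rng.uniform(0.8, 1.2) for _ in range(3)]
    f = np.vstack(rows)
    ids = [f"r{i}" for i in range(3)] + [f"f{i}" for i in range(3)]
    return FrequencyMatrix(ids, np.arange(5.0), f, 1e-6, filtered=True)


class TestCallClonalClusters:
    def test_ranking_by_final_abundance(self):
        fm = two_family_freqs()
        dm = build_distance_matrix(fm, "pearson", "log10_floored")
        T = transform_trajectories(fm, "log10_floored")
        tree = linkage(dm)
        cs = call_clonal_clusters(fm, dm, tree, tree.max_height / 2)
        assert cs.n_clusters == 2
        # risers end high -> C1 holds the r* barcodes
        assert set(cs.members("C1")) == {"r0", "r1", "r2"}
        assert cs.final_frequency["C1"] > cs.final_frequency["C2"]
        assert cs.rank == ["C1", "C2"]

    def test_every_barcode_assigned_once(self):
        fm = two_family_freqs()
        dm = build_distance_matrix(fm)
        tree = linkage(dm)
        cs = call_clonal_clusters(fm, dm, tree, 0.05)
        assert sorted(cs.assignment) == sorted(fm.barcode_ids)
        ranks = cs.assignment_frame()["rank"]
        assert set(cs.rank) == set(cs.assignment.values())

    def test_tie_broken_by_smallest_member_id(self):
        # two singleton clusters with exactly equal final frequency
        f = np.array([[0.1, 0.3, 0.25], [0.42, 0.18, 0.25], [0.48, 0.52, 0.5]])
        fm = FrequencyMatrix(["x", "a", "z"], np.arange(3.0), f, 1e-6)
        dm = build_distance_matrix(fm, "pearson", "linear")
        tree = linkage(dm)
        cs = call_clonal_clusters(fm, dm, tree, 0.0)
        assert cs.rank[0] == "C1"
        first_two = [cs.assignment["a"], cs.assignment["x"]]
        # equal finals 0.25/0.25: 'a' precedes 'x'
        assert cs.final_frequency[cs.assignment["a"]] == pytest.approx(0.25)
        assert first_two == sorted(first_two)

    def test_minor_flagging(self):
        fm = two_family_freqs()
        dm = build_distance_matrix(fm)
        tree = linkage(dm)
        cs = call_clonal_clusters(fm, dm, tree, tree.max_height / 2,
                                  min_cluster_frequency=0.9)
        assert all(cs.minor.values())  # nothing reaches 90%

    def test_consensus_on_frequency_scale(self):
        fm = two_family_freqs()
        dm = build_distance_matrix(fm)
        tree = linkage(dm)
        cs = call_clonal_clusters(fm, dm, tree, tree.max_height / 2)
        vals = cs.consensus["frequency"]
        assert (vals >= fm.floor).all() and (vals <= 1.0).all()


class TestClonalClustererEstimator:
    def test_fit_predict_two_families(self):
        fm = two_family_freqs()
        est = ClonalClusterer(cut_height=0.5, floor=1e-6)
        labels = est.fit_predict(fm.freqs)
        assert est.labels_.shape == (6,)
        # rank order: label 0 is the most abundant final cluster (risers)
        assert set(labels[:3]) == {0} and set(labels[3:]) == {1}
        assert est.cut_height_ == 0.5
        assert est.clusters_.n_clusters == 2

    def test_auto_threshold_path(self):
        fm = two_family_freqs()
        est = ClonalClusterer(auto_threshold="plateau").fit(fm.freqs)
        assert 0 <= est.cut_height_ <= est.linkage_tree_.max_height
        assert est.quantification_.n_clusters[-1] == 1

    def test_sklearn_clone_and_params(self):
        est = ClonalClusterer(metric="dtw", grid_size=17)
        est2 = clone(est)
        assert est2.get_params()["metric"] == "dtw"
        assert est2.get_params()["grid_size"] == 17
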