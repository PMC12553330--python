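"""Hierarchical clustering of barcode trajectories and the clonal-cluster caller.

Trajectories that move together reflect comparable relative fitness, so
dominant clonal lineages are found by agglomerative clustering of the
pairwise trajectory-distance matrix:

* ``linkage`` builds the merge tree with UPGMA (unweighted average linkage on
  the distance matrix) or UPGMC (centroid linkage in the transformed
  trajectory space);
* ``quantify_thresholds`` sweeps cut heights and records cluster counts and
  centroid separation, supporting the user's threshold choice;
* ``cut`` extracts a flat clustering at a chosen height;
* ``call_clonal_clusters`` summarizes each cluster by a LOESS consensus
  trajectory and ranks clusters C1, C2, ... by their summed member frequency
  at the final timepoint.

Tie-breaking is deterministic throughout: leaves are ordered
lexicographically by barcode ID and cluster labels are assigned by each
cluster's smallest member ID, so repeated runs are bit-reproducible.

``ClonalClusterer`` wraps the whole chain as a scikit-learn cluster
estimator over a plain (n_barcodes x n_timepoints) frequency array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .core import FrequencyMatrix
from .distance import TrajectoryDistanceMatrix, _dtw_matrix, _pearson_matrix, transform_trajectories
from .smoothing import loess_consensus

__all__ = [
    "LinkageTree",
    "ClusterQuantification",
    "ClonalClusterSet",
    "ClonalClusterer",
    "linkage",
    "cut",
    "quantify_thresholds",
    "call_clonal_clusters",
    "select_threshold",
]


@dataclass(frozen=True)
class LinkageTree:
    """Agglomerative merge history over lexicographically ordered leaves.

    ``merges`` is the scipy linkage matrix: row i merges nodes
    ``merges[i, 0]`` and ``merges[i, 1]`` (leaves are 0..n-1, internal nodes
    n+i) at height ``merges[i, 2]`` into a cluster of size ``merges[i, 3]``.
    """

    merges: np.ndarray
    leaf_ids: list[str]
    method: str  # "upgma" | "upgmc"

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def max_height(self) -> float:
        return float(self.merges[:, 2].max()) if len(self.merges) else 0.0

    def cut(self, height: float) -> dict[str, int]:
        return cut(self, height)

    def to_newick(self) -> str:
        """Newick string with merge heights as cumulative node depths.

        Branch lengths are parent height minus child height, so leaf-to-root
        path length equals the root merge height.
        """
        n = self.n_leaves
        if n == 1:
            return f"{_nw_escape(self.leaf_ids[0])}:0;"
        rep = {i: (_nw_escape(self.leaf_ids[i]), 0.0) for i in range(n)}
        for i, (a, b, h, _) in enumerate(self.merges):
            (sa, ha), (sb, hb) = rep.pop(int(a)), rep.pop(int(b))
            rep[n + i] = (f"({sa}:{h - ha:g},{sb}:{h - hb:g})", float(h))
        (root, _), = rep.values()
        return root + ";"


def _nw_escape(name: str) -> str:
    if any(c in name for c in " (),:;'"):
        return "'" + name.replace("'", "''") + "'"
    return name


@dataclass(frozen=True)
class ClusterQuantification:
    """Cluster count and centroid separation over a grid of cut heights."""

    thresholds: np.ndarray
    n_clusters: np.ndarray
    centroid_separation: np.ndarray  # NaN where a single cluster remains

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "n_clusters": self.n_clusters,
                "centroid_separation": self.centroid_separation,
            }
        )


@dataclass(frozen=True)
class ClonalClusterSet:
    """Flat clustering with LOESS consensus trajectories and abundance ranks.

    Clusters are named C1, C2, ... in order of decreasing summed member
    frequency at the final timepoint (ties broken by smallest member ID).
    Clusters below ``min_cluster_frequency`` at the final timepoint are
    flagged minor, never dropped.
    """

    assignment: dict[str, str]  # barcode ID -> cluster name
    consensus: pd.DataFrame  # columns: cluster, Time, frequency
    rank: list[str]  # cluster names in rank order C1, C2, ...
    final_frequency: dict[str, float]
    minor: dict[str, bool]
    cut_height: float
    timepoints: np.ndarray = field(repr=False)

    @property
    def n_clusters(self) -> int:
        return len(self.rank)

    def members(self, cluster: str) -> list[str]:
        return sorted(b for b, c in self.assignment.items() if c == cluster)

    def assignment_frame(self) -> pd.DataFrame:
        ranks = {c: i + 1 for i, c in enumerate(self.rank)}
        rows = [
            {"ID": b, "cluster": c, "rank": ranks[c], "minor": self.minor[c]}
            for b, c in sorted(self.assignment.items())
        ]
        return pd.DataFrame(rows)


def linkage(
    dm: TrajectoryDistanceMatrix,
    method: str = "upgma",
    trajectories: np.ndarray | None = None,
) -> LinkageTree:
    """Build the agglomerative merge tree.

    UPGMA merges the pair of clusters with the smallest unweighted mean of
    cross-pair distances; UPGMC merges by Euclidean distance between cluster
    centroids in the transformed trajectory space (``trajectories`` required;
    the precomputed distance matrix is not used because correlation distance
    is not Euclidean).
    """
    if dm.n < 2:
        raise ValueError("need at least 2 leaves")
    if np.any(np.isnan(dm.d)):
        raise ValueError("distance matrix contains NaN")
    order = np.argsort(np.asarray(dm.ids, dtype=object), kind="stable")
    ids = [dm.ids[i] for i in order]
    if method == "upgma":
        d = dm.d[np.ix_(order, order)]
        Z = sch.linkage(squareform(d, checks=False), method="average")
    elif method == "upgmc":
        if trajectories is None:
            raise ValueError("UPGMC requires the transformed trajectory matrix")
        T = np.asarray(trajectories, dtype=float)[order]
        Z = sch.linkage(T, method="centroid")
    else:
        raise ValueError(f"unknown linkage method {method!r}")
    return LinkageTree(Z, ids, method)


def cut(tree: LinkageTree, height: float) -> dict[str, int]:
    """Flat clusters at a cut height (merges with height <= cut are kept).

    Labels are consecutive integers starting at 0, assigned in order of each
    cluster's lexicographically smallest member ID.
    """
    if height < 0:
        raise ValueError("cut height must be >= 0")
    raw = sch.fcluster(tree.merges, t=height, criterion="distance")
    return dict(zip(tree.leaf_ids, _relabel(raw, tree.leaf_ids)))


def _relabel(raw: np.ndarray, ids: list[str]) -> np.ndarray:
    """Renumber cluster labels by each cluster's smallest member ID."""
    first = {}
    for i, lab in enumerate(raw):
        if lab not in first or str(ids[i]) < str(ids[first[lab]]):
            first[lab] = i
    ordered = sorted(first, key=lambda lab: str(ids[first[lab]]))
    remap = {lab: k for k, lab in enumerate(ordered)}
    return np.array([remap[lab] for lab in raw], dtype=int)


def _centroid_separation(
    labels: np.ndarray, trajectories: np.ndarray, metric: str
) -> float:
    k = labels.max() + 1
    if k < 2:
        return float("nan")
    centroids = np.vstack(
        [trajectories[labels == c].mean(axis=0) for c in range(k)]
    )
    try:
        if metric == "pearson":
            d = _pearson_matrix(centroids)
        else:
            d = _dtw_matrix(centroids, None)
    except ValueError:  # e.g. a constant centroid under pearson
        return float("nan")
    iu = np.triu_indices(k, 1)
    return float(d[iu].min())


def quantify_thresholds(
    tree: LinkageTree,
    dm: TrajectoryDistanceMatrix,
    trajectories: np.ndarray,
    grid_size: int = 100,
) -> ClusterQuantification:
    """Sweep an even grid of cut heights from 0 to the maximum merge height.

    Per cut: the number of clusters and the minimum pairwise distance between
    cluster mean trajectories (centroids), under the matrix's metric.
    ``trajectories`` must be row-aligned with ``dm.ids``.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    order = np.argsort(np.asarray(dm.ids, dtype=object), kind="stable")
    T = np.asarray(trajectories, dtype=float)[order]
    grid = np.linspace(0.0, tree.max_height, grid_size)
    n_clusters = np.empty(grid_size, dtype=int)
    sep = np.empty(grid_size)
    for i, h in enumerate(grid):
        raw = sch.fcluster(tree.merges, t=h, criterion="distance")
        labels = raw - 1
        n_clusters[i] = labels.max() + 1
        sep[i] = _centroid_separation(labels, T, dm.metric)
    return ClusterQuantification(grid, n_clusters, sep)


def select_threshold(quant: ClusterQuantification, rule: str = "knee") -> float:
    """Convenience cut-height heuristics over a threshold sweep.

    ``knee`` picks the grid point maximizing the second difference of the
    cluster count (where the count curve flattens); ``plateau`` picks the
    midpoint of the longest run of a constant non-trivial cluster count.
    Threshold choice is fundamentally the user's; these are aids.
    """
    n = quant.n_clusters.astype(float)
    if rule == "knee":
        if n.size < 3:
            return float(quant.thresholds[-1])
        d2 = n[2:] - 2 * n[1:-1] + n[:-2]
        return float(quant.thresholds[1 + int(np.argmax(d2))])
    if rule == "plateau":
        best = (0, None)  # (run length, start index)
        i = 0
        while i < n.size:
            j = i
            while j + 1 < n.size and n[j + 1] == n[i]:
                j += 1
            run = j - i + 1
            nontrivial = 1 < n[i] < n[0]
            if nontrivial and run > best[0]:
                best = (run, i)
            i = j + 1
        if best[1] is None:
            return float(quant.thresholds[n.size // 2])
        i = best[1]
        return float(quant.thresholds[i + best[0] // 2])
    raise ValueError(f"unknown threshold rule {rule!r}")


def call_clonal_clusters(
    fm: FrequencyMatrix,
    dm: TrajectoryDistanceMatrix,
    tree: LinkageTree,
    height: float,
    span: float = 0.75,
    degree: int = 2,
    min_cluster_frequency: float = 0.01,
) -> ClonalClusterSet:
    """Cut the tree, build per-cluster LOESS consensus, rank by final abundance.

    The consensus is fitted on the same transform used for clustering
    (log10-floored or linear) and reported on the frequency scale,
    back-transformed and floored at the detection floor when log. Clusters
    whose summed member frequency at the final timepoint is below
    ``min_cluster_frequency`` are flagged minor.
    """
    if not 0 <= height <= max(tree.max_height, 0) * (1 + 1e-12) + 1e-12:
        raise ValueError("cut height outside [0, max merge height]")
    if set(fm.barcode_ids) != set(dm.ids):
        raise ValueError("frequency matrix and distance matrix disagree on barcodes")
    assignment_int = cut(tree, height)
    idx = {b: i for i, b in enumerate(fm.barcode_ids)}
    T = transform_trajectories(fm, dm.transform)
    k = max(assignment_int.values()) + 1
    members = {c: [b for b, lab in assignment_int.items() if lab == c] for c in range(k)}

    final = {
        c: float(sum(fm.freqs[idx[b], -1] for b in mem)) for c, mem in members.items()
    }
    # rank by descending final abundance; ties by smallest member ID
    order = sorted(members, key=lambda c: (-final[c], min(members[c])))
    names = {c: f"C{r + 1}" for r, c in enumerate(order)}

    rows = []
    for c in range(k):
        mem_idx = [idx[b] for b in members[c]]
        cons = loess_consensus(T[mem_idx], fm.timepoints, span=span, degree=degree)
        if dm.transform == "log10_floored":
            cons = np.clip(10.0**cons, fm.floor, 1.0)
        for t, v in zip(fm.timepoints, cons):
            rows.append({"cluster": names[c], "Time": t, "frequency": v})
    consensus = pd.DataFrame(rows).sort_values(
        ["cluster", "Time"], key=lambda s: s.map(_rank_key) if s.name == "cluster" else s
    ).reset_index(drop=True)

    return ClonalClusterSet(
        assignment={b: names[lab] for b, lab in assignment_int.items()},
        consensus=consensus,
        rank=[names[c] for c in order],
        final_frequency={names[c]: final[c] for c in range(k)},
        minor={names[c]: final[c] < min_cluster_frequency for c in range(k)},
        cut_height=float(height),
        timepoints=fm.timepoints,
    )


def _rank_key(name: str) -> int:
    return int(name[1:]) if name.startswith("C") and name[1:].isdigit() else 0


class ClonalClusterer(ClusterMixin, BaseEstimator):
    """Dominant clonal lineage caller as a scikit-learn cluster estimator.

    ``fit(X)`` takes the (filtered) frequency matrix, rows = barcodes,
    columns = shared timepoints, and runs the chain distance matrix ->
    linkage -> threshold sweep -> cut -> LOESS consensus -> abundance
    ranking. Row index i is identified by the zero-padded string ``B%06d``
    for deterministic tie-breaking; use the module-level functions for real
    barcode IDs.

    Parameters
    ----------
    metric : {"pearson", "dtw"}, default="pearson"
    trajectory_transform : {"log10_floored", "linear"}, default="log10_floored"
    floor : float, default=1e-6
        Zero replacement on the log scale.
    window : int or None
        DTW Sakoe-Chiba half-width.
    linkage_method : {"upgma", "upgmc"}, default="upgma"
    cut_height : float or None
        Explicit cut height; when None, chosen by ``auto_threshold``.
    auto_threshold : {"knee", "plateau"}, default="knee"
    grid_size : int, default=100
        Cut-height grid for the threshold sweep.
    loess_span, loess_degree : LOESS consensus parameters.
    min_cluster_frequency : float, default=0.01
        Minor-cluster flagging threshold on final summed frequency.

    Attributes
    ----------
    labels_ : ndarray of int
        Cluster index per barcode, 0-based in rank order (0 is the most
        abundant cluster at the final timepoint).
    distance_matrix_ : ndarray
    linkage_tree_ : LinkageTree
    quantification_ : ClusterQuantification
    cut_height_ : float
    clusters_ : ClonalClusterSet
    """

    def __init__(
        self,
        metric: str = "pearson",
        trajectory_transform: str = "log10_floored",
        floor: float = 1e-6,
        window: int | None = None,
        linkage_method: str = "upgma",
        cut_height: float | None = None,
        auto_threshold: str = "knee",
        grid_size: int = 100,
        loess_span: float = 0.75,
        loess_degree: int = 2,
        min_cluster_frequency: float = 0.01,
    ):
        self.metric = metric
        self.trajectory_transform = trajectory_transform
        self.floor = floor
        self.window = window
        self.linkage_method = linkage_method
        self.cut_height = cut_height
        self.auto_threshold = auto_threshold
        self.grid_size = grid_size
        self.loess_span = loess_span
        self.loess_degree = loess_degree
        self.min_cluster_frequency = min_cluster_frequency

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        ids = [f"B{i:06d}" for i in range(X.shape[0])]
        fm = FrequencyMatrix(ids, np.arange(X.shape[1], dtype=float), X,
                             self.floor, filtered=True)
        from .distance import build_distance_matrix  # local to avoid cycle noise

        dm = build_distance_matrix(fm, self.metric, self.trajectory_transform,
                                   self.window)
        T = transform_trajectories(fm, self.trajectory_transform)
        tree = linkage(dm, self.linkage_method,
                       trajectories=T if self.linkage_method == "upgmc" else None)
        quant = quantify_thresholds(tree, dm, T, self.grid_size)
        h = (
            float(self.cut_height)
            if self.cut_height is not None
            else select_threshold(quant, self.auto_threshold)
        )
        cs = call_clonal_clusters(
            fm, dm, tree, h,
            span=self.loess_span, degree=self.loess_degree,
            min_cluster_frequency=self.min_cluster_frequency,
        )
        self.n_features_in_ = X.shape[1]
        self.distance_matrix_ = dm.d
        self.linkage_tree_ = tree
        self.quantification_ = quant
        self.cut_height_ = h
        self.clusters_ = cs
        rank_index = {name: r for r, name in enumerate(cs.rank)}
        self.labels_ = np.array([rank_index[cs.assignment[b]] for b in ids])
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
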