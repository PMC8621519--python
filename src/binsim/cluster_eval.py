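"""Clustering and ground-truth clustering-quality metrics.

Replicate groups (e.g. the three biological replicates of each genotype or
strain) define the ground truth that an unsupervised method should recover.
UPGMA hierarchical clustering is scored by the correct-clustering
percentage, the correct-first-cluster percentage and the Discrimination
Distance; K-means (with restarts, minimum-inertia solution) by the
correct-clustering percentage, its own Discrimination Distance and the
adjusted Rand index.  Dendrograms from different pre-treatments are compared
by the cophenetic correlation and Baker's gamma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .binary_distances import DistanceMatrix

__all__ = [
    "Dendrogram",
    "Partition",
    "ClusteringReport",
    "hca",
    "correct_clustering_hca",
    "discrimination_distance_hca",
    "correct_first_cluster",
    "kmeans",
    "correct_clustering_kmeans",
    "discrimination_distance_kmeans",
    "adjusted_rand",
    "cophenetic_correlation",
    "bakers_gamma",
    "hca_report",
    "kmeans_report",
]


@dataclass(frozen=True)
class Dendrogram:
    """An agglomeration tree: scipy linkage matrix plus leaf identities.

    Nodes are numbered scipy-style: leaves ``0..n-1`` in ``leaf_ids`` order,
    internal node ``n + i`` created by merge row ``i`` of ``Z``.
    """

    leaf_ids: tuple
    Z: np.ndarray

    def __post_init__(self) -> None:
        Z = np.asarray(self.Z, dtype=float)
        object.__setattr__(self, "Z", Z)
        object.__setattr__(self, "leaf_ids", tuple(self.leaf_ids))
        n = len(self.leaf_ids)
        if Z.shape != (n - 1, 4):
            raise ValueError("linkage matrix must have n-1 rows for n leaves")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def node_heights(self) -> np.ndarray:
        """Height of every node (leaves at 0)."""
        return np.concatenate([np.zeros(self.n_leaves), self.Z[:, 2]])

    def node_leaf_sets(self) -> list:
        """Leaf-index set of every node, in node-number order."""
        n = self.n_leaves
        sets: list[frozenset] = [frozenset([i]) for i in range(n)]
        for a, b, *_ in self.Z:
            sets.append(sets[int(a)] | sets[int(b)])
        return sets

    def cophenetic_matrix(self) -> pd.DataFrame:
        """Pairwise heights of lowest common nodes, labelled by leaf id."""
        dm = squareform(cophenet(self.Z))
        return pd.DataFrame(dm, index=self.leaf_ids, columns=self.leaf_ids)

    def to_newick(self) -> str:
        """Newick string; branch lengths from merge-height differences."""
        n = self.n_leaves
        heights = self.node_heights()

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - heights[node]
            if node < n:
                return f"{self.leaf_ids[node]}:{bl:g}"
            a, b = int(self.Z[node - n, 0]), int(self.Z[node - n, 1])
            h = heights[node]
            return f"({render(a, h)},{render(b, h)}):{bl:g}"

        root = 2 * n - 2
        a, b = int(self.Z[-1, 0]), int(self.Z[-1, 1])
        h = heights[root]
        return f"({render(a, h)},{render(b, h)});"


@dataclass(frozen=True)
class Partition:
    """A flat clustering: sample -> cluster id, with optional centroids."""

    assignment: dict
    centroids: np.ndarray | None = None
    inertia: float | None = None

    @property
    def sample_ids(self) -> tuple:
        return tuple(self.assignment)

    def clusters(self) -> dict:
        """cluster id -> frozenset of sample ids."""
        out: dict = {}
        for s, c in self.assignment.items():
            out.setdefault(c, set()).add(s)
        return {c: frozenset(v) for c, v in out.items()}


@dataclass(frozen=True)
class ClusteringReport:
    correct_clustering_pct: float
    discrimination_distance: float
    correct_first_cluster_pct: float | None = None  # HCA only
    rand_index: float | None = None                 # K-means only


def _group_sets(gt, sample_ids) -> dict:
    """group id -> frozenset of leaf/sample indices within ``sample_ids``."""
    gt = dict(gt)
    missing = [s for s in sample_ids if s not in gt]
    if missing:
        raise ValueError(f"ground truth missing for samples: {missing}")
    out: dict = {}
    for i, s in enumerate(sample_ids):
        out.setdefault(gt[s], set()).add(i)
    return {g: frozenset(v) for g, v in out.items()}


# --------------------------------------------------------------------------
# Hierarchical clustering
# --------------------------------------------------------------------------

def hca(d: DistanceMatrix) -> Dendrogram:
    """UPGMA (average-linkage) agglomeration of a distance matrix."""
    if d.n_samples < 2:
        raise ValueError("clustering requires at least two samples")
    Z = linkage(d.condensed, method="average")
    return Dendrogram(d.sample_ids, Z)


def correct_clustering_hca(dend: Dendrogram, gt) -> float:
    """Percent of groups whose samples form a node before mixing with others.

    A group is correct iff some node of the tree contains exactly its
    samples (purity and completeness at once); singleton groups are
    trivially correct through their leaf.
    """
    groups = _group_sets(gt, dend.leaf_ids)
    node_sets = set(dend.node_leaf_sets())
    correct = sum(1 for members in groups.values() if members in node_sets)
    return 100.0 * correct / len(groups)


def discrimination_distance_hca(dend: Dendrogram, gt) -> float:
    """Mean normalized margin between each pure-group node and its absorption.

    For a correctly clustered group, the margin is the height of the merge
    that absorbs the pure-group node minus the height of that node,
    normalized by the maximum merge height of the tree; incorrectly
    clustered groups contribute 0, as does a pure node that is already the
    root (nothing ever absorbs it).
    """
    groups = _group_sets(gt, dend.leaf_ids)
    node_sets = dend.node_leaf_sets()
    heights = dend.node_heights()
    n = dend.n_leaves
    max_h = float(dend.Z[:, 2].max())
    if max_h == 0:
        return 0.0
    # node -> merge row that absorbs it
    absorbed_at = {}
    for i, (a, b, h, _) in enumerate(dend.Z):
        absorbed_at[int(a)] = h
        absorbed_at[int(b)] = h
    dd = []
    for members in groups.values():
        try:
            node = node_sets.index(members)
        except ValueError:
            dd.append(0.0)
            continue
        if node not in absorbed_at:  # pure node is the root
            dd.append(0.0)
            continue
        dd.append((absorbed_at[node] - heights[node]) / max_h)
    return float(np.mean(dd))


def correct_first_cluster(dend: Dendrogram, gt) -> float:
    """Percent of samples whose first merge joins only own-group samples."""
    gt = dict(gt)
    groups = _group_sets(gt, dend.leaf_ids)
    node_sets = dend.node_leaf_sets()
    n = dend.n_leaves
    correct = 0
    for leaf in range(n):
        row = np.where((dend.Z[:, 0] == leaf) | (dend.Z[:, 1] == leaf))[0][0]
        a, b = int(dend.Z[row, 0]), int(dend.Z[row, 1])
        sibling = b if a == leaf else a
        own = groups[gt[dend.leaf_ids[leaf]]]
        if node_sets[sibling] <= own:
            correct += 1
    return 100.0 * correct / n


# --------------------------------------------------------------------------
# K-means
# --------------------------------------------------------------------------

def _numeric_matrix(mat):
    """(values, sample_ids) from BinaryMatrix / PeakTable / DataFrame / array."""
    if isinstance(mat, DistanceMatrix):
        raise TypeError("K-means operates on sample coordinates, not a distance matrix")
    if hasattr(mat, "data") and hasattr(mat, "sample_ids"):  # PeakTable / BinaryMatrix
        return np.asarray(mat.values, dtype=float), list(mat.sample_ids)
    if isinstance(mat, pd.DataFrame):
        return mat.to_numpy(dtype=float), list(mat.index)
    X = np.asarray(mat, dtype=float)
    return X, [str(i) for i in range(X.shape[0])]


def kmeans(mat, k: int, n_init: int = 15, seed: int = 0) -> Partition:
    """Euclidean K-means: Lloyd iterations from ``n_init`` random starts.

    The minimum-inertia solution over the restarts is returned.  Binary
    matrices are clustered in the same Euclidean geometry as intensity data.
    """
    X, ids = _numeric_matrix(mat)
    if np.isnan(X).any():
        raise ValueError("K-means requires a fully observed matrix")
    if not 1 <= k <= X.shape[0]:
        raise ValueError(f"k must be in [1, n_samples={X.shape[0]}]")
    km = KMeans(n_clusters=k, init="random", n_init=n_init, algorithm="lloyd",
                random_state=seed)
    labels = km.fit_predict(X)
    return Partition(
        assignment={s: int(c) for s, c in zip(ids, labels)},
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
    )


def correct_clustering_kmeans(p: Partition, gt) -> float:
    """Percent of groups matched exactly by some cluster (homogeneity and
    completeness together)."""
    gt = dict(gt)
    groups: dict = {}
    for s in p.sample_ids:
        groups.setdefault(gt[s], set()).add(s)
    clusters = set(p.clusters().values())
    correct = sum(1 for members in groups.values() if frozenset(members) in clusters)
    return 100.0 * correct / len(groups)


def discrimination_distance_kmeans(p: Partition, gt) -> float:
    """Mean normalized centroid margin of correctly clustered groups.

    For each correct group: distance from its cluster centroid to the
    nearest other centroid, over the maximum pairwise centroid distance.
    """
    if p.centroids is None:
        raise ValueError("partition has no centroids")
    C = np.asarray(p.centroids, dtype=float)
    if C.shape[0] < 2:
        return 0.0
    D = squareform(pdist(C))
    max_d = D.max()
    if max_d == 0:
        return 0.0
    gt = dict(gt)
    groups: dict = {}
    for s in p.sample_ids:
        groups.setdefault(gt[s], set()).add(s)
    clusters = p.clusters()
    dd = []
    for members in groups.values():
        match = [c for c, ms in clusters.items() if ms == frozenset(members)]
        if not match:
            dd.append(0.0)
            continue
        c = match[0]
        others = np.delete(D[c], c)
        dd.append(float(others.min() / max_d))
    return float(np.mean(dd))


def adjusted_rand(p: Partition, gt) -> float:
    """Adjusted Rand index between a partition and the ground truth."""
    gt = dict(gt)
    samples = list(p.sample_ids)
    true = [gt[s] for s in samples]
    pred = [p.assignment[s] for s in samples]
    return float(adjusted_rand_score(true, pred))


# --------------------------------------------------------------------------
# Dendrogram comparison
# --------------------------------------------------------------------------

def cophenetic_correlation(d1: Dendrogram, d2: Dendrogram) -> float:
    """Pearson correlation of the two trees' pairwise cophenetic distances."""
    if set(d1.leaf_ids) != set(d2.leaf_ids):
        raise ValueError("dendrograms must share the same leaf set")
    m1 = d1.cophenetic_matrix()
    m2 = d2.cophenetic_matrix().loc[list(d1.leaf_ids), list(d1.leaf_ids)]
    v1 = squareform(m1.to_numpy(), checks=False)
    v2 = squareform(m2.to_numpy(), checks=False)
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("cophenetic correlation undefined for a constant distance vector")
    return float(np.corrcoef(v1, v2)[0, 1])


def _co_cluster_levels(dend: Dendrogram) -> np.ndarray:
    """For every leaf pair, the cluster count k at which the pair first
    co-clusters when cutting the tree into k groups (condensed order of
    ``dend.leaf_ids``)."""
    n = dend.n_leaves
    node_sets = dend.node_leaf_sets()
    level = np.zeros((n, n))
    # merge row m (1-based) leaves n - m clusters; a pair co-clusters from
    # the row that first joins them.  Tied merge heights cannot be separated
    # by any cut, so every merge in a tie block takes the block's last index
    # (making the levels invariant to tie ordering).
    heights = dend.Z[:, 2]
    block_end = np.empty(n - 1, dtype=int)
    m = n - 2
    while m >= 0:
        end = m
        while m >= 0 and heights[m] == heights[end]:
            m -= 1
        block_end[m + 1:end + 1] = end + 1  # 1-based index of block end
    for row, (a, b, *_) in enumerate(dend.Z):
        lvl = n - block_end[row]
        for i in node_sets[int(a)]:
            for j in node_sets[int(b)]:
                level[i, j] = level[j, i] = lvl
    return squareform(level, checks=False)


def bakers_gamma(d1: Dendrogram, d2: Dendrogram) -> float:
    """Baker's gamma: rank correlation of per-pair co-clustering levels.

    Invariant to monotone transformations of merge heights, so it compares
    tree topology/order rather than scale.
    """
    if set(d1.leaf_ids) != set(d2.leaf_ids):
        raise ValueError("dendrograms must share the same leaf set")
    if d1.n_leaves < 3:
        raise ValueError("Baker's gamma requires at least three leaves")
    v1 = _co_cluster_levels(d1)
    # recompute d2 levels in d1's leaf order
    order = [d2.leaf_ids.index(s) for s in d1.leaf_ids]
    lvl2 = squareform(_co_cluster_levels(d2))[np.ix_(order, order)]
    v2 = squareform(lvl2, checks=False)
    rho = spearmanr(v1, v2).statistic
    return float(rho)


# --------------------------------------------------------------------------
# Reports
# --------------------------------------------------------------------------

def hca_report(dend: Dendrogram, gt) -> ClusteringReport:
    return ClusteringReport(
        correct_clustering_pct=correct_clustering_hca(dend, gt),
        discrimination_distance=discrimination_distance_hca(dend, gt),
        correct_first_cluster_pct=correct_first_cluster(dend, gt),
    )


def kmeans_report(p: Partition, gt) -> ClusteringReport:
    return ClusteringReport(
        correct_clustering_pct=correct_clustering_kmeans(p, gt),
        discrimination_distance=discrimination_distance_kmeans(p, gt),
        rand_index=adjusted_rand(p, gt),
    )
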