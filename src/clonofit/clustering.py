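"""Classification of cell lines by hierarchical clustering.

The panel's mean-SF matrix (cell lines x nonzero doses, in percent) is
reduced to pairwise Euclidean distances and agglomerated with Ward's
method, which at each stage fuses the pair of clusters whose merger adds
the least within-cluster error sum of squares (ESS).  The merge heights
of the resulting dendrogram guide the choice of the number of clusters
(the best cut sits below the largest jump in fusion level), and the
silhouette width of each cell line quantifies how well it sits in its
cluster.

Two Ward conventions circulate.  The default ("ward") applies the
Lance-Williams update to squared Euclidean distances, so merge costs
track the ESS increase directly (heights are sqrt(2 * delta-ESS)); the
alternative ("ward_d") applies the same update to the raw distances.
Both are available; they can order merges differently on some inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_samples

from .dataio import SurvivalDataset, mean_sf_matrix
from .errors import ValidationError

LINKAGES = ("ward", "ward_d", "single", "complete", "average")


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray = field(repr=False)  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValidationError(f"distance matrix must be {n}x{n}, got {d.shape}")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(d < 0):
            raise ValidationError("distances must be non-negative")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        object.__setattr__(self, "d", d)

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration result: a scipy linkage matrix plus leaf labels.

    ``merges`` rows are (cluster_a, cluster_b, height, size) with leaves
    numbered 0..n-1 in label order and internal nodes n, n+1, ...
    """

    labels: tuple[str, ...]
    merges: np.ndarray = field(repr=False)  # scipy linkage matrix, (n-1) x 4

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass(frozen=True)
class ClusterSolution:
    k: int
    labels: dict[str, int]  # cell line -> cluster id (1..k)


@dataclass(frozen=True)
class SilhouetteResult:
    s: dict[str, float]  # per-line silhouette width in [-1, 1]
    average: float


def feature_variants(ds: SurvivalDataset, mode: str = "raw_percent") -> pd.DataFrame:
    """Feature matrix for clustering.

    ``raw_percent``: mean SF in percent (lines x nonzero doses);
    ``log``: natural log of the mean SF as a fraction;
    ``sf2_only``: single column, the mean SF (percent) at 2 Gy.
    """
    mat = mean_sf_matrix(ds)
    if mode == "raw_percent":
        return mat
    if mode == "log":
        return np.log(mat / 100.0)
    if mode == "sf2_only":
        if 2.0 not in [float(c) for c in mat.columns]:
            raise ValidationError("sf2_only requires dose 2 Gy in the grid")
        return mat.loc[:, [c for c in mat.columns if float(c) == 2.0]]
    raise ValidationError(f"unknown feature mode {mode!r}")


def euclidean_distances(X: pd.DataFrame | np.ndarray, labels=None) -> DistanceMatrix:
    """Pairwise Euclidean distances between the rows of ``X``."""
    if isinstance(X, pd.DataFrame):
        labels = tuple(str(i) for i in X.index)
        arr = X.to_numpy(float)
    else:
        arr = np.asarray(X, dtype=float)
        labels = tuple(labels) if labels is not None else tuple(
            str(i) for i in range(arr.shape[0])
        )
    if np.isnan(arr).any():
        raise ValidationError("feature matrix contains missing values")
    return DistanceMatrix(labels, squareform(pdist(arr), checks=False))


def agglomerate(D: DistanceMatrix, linkage: str = "ward") -> Dendrogram:
    """Agglomerative hierarchical clustering of a distance matrix.

    ``ward`` runs the squared-distance Lance-Williams update (heights
    are interpretable against the ESS criterion on Euclidean input);
    ``ward_d`` runs the classical update on raw distances, obtained here
    by feeding sqrt-distances to the squared-form algorithm and squaring
    the resulting heights.  Other linkages pass through unchanged.
    """
    if D.d.shape[0] < 2:
        raise ValidationError("need at least two objects to agglomerate")
    cond = D.condensed()
    if linkage == "ward":
        Z = hierarchy.linkage(cond, method="ward")
    elif linkage == "ward_d":
        Z = hierarchy.linkage(np.sqrt(cond), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2
    elif linkage in ("single", "complete", "average"):
        Z = hierarchy.linkage(cond, method=linkage)
    else:
        raise ValidationError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    return Dendrogram(labels=D.labels, merges=Z)


def cut_tree(dend: Dendrogram, k: int) -> ClusterSolution:
    """Partition into exactly ``k`` clusters by cutting below the
    (n - k + 1)-th merge.  Cluster ids are 1..k in order of first leaf."""
    n = dend.n_leaves
    if not (1 <= k <= n):
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    flat = hierarchy.cut_tree(dend.merges, n_clusters=k).ravel()
    # relabel to 1..k in order of first appearance for determinism
    remap: dict[int, int] = {}
    labels = {}
    for name, cid in zip(dend.labels, flat):
        if cid not in remap:
            remap[cid] = len(remap) + 1
        labels[name] = remap[cid]
    return ClusterSolution(k=k, labels=labels)


def best_cut(dend: Dendrogram, k_max: int | None = None) -> ClusterSolution:
    """Cut at the largest gap between consecutive fusion levels.

    For k clusters the relevant gap is between the (n-k)-th and
    (n-k+1)-th merge heights; k ranges over 2..k_max (default n-1, so a
    trivial all-singletons solution is never proposed for n > 2).  Ties
    go to the smaller k.
    """
    n = dend.n_leaves
    if n < 2:
        raise ValidationError("need at least two leaves")
    if n == 2:
        return cut_tree(dend, 2)
    h = dend.heights
    k_hi = k_max if k_max is not None else n - 1
    k_hi = min(k_hi, n - 1)
    best_k, best_gap = 2, -np.inf
    for k in range(2, k_hi + 1):
        gap = h[n - k] - h[n - k - 1]
        if gap > best_gap + 1e-12:
            best_gap = gap
            best_k = k
    return cut_tree(dend, best_k)


def silhouette(D: DistanceMatrix, sol: ClusterSolution) -> SilhouetteResult:
    """Silhouette widths s_i = (b_i - a_i)/max(a_i, b_i).

    a_i is the mean distance of object i to the other members of its
    cluster, b_i the smallest mean distance to any other cluster; members
    of singleton clusters get s_i = 0 by convention.
    """
    if sol.k < 2:
        raise ValidationError("silhouette undefined for a single cluster")
    order = list(D.labels)
    y = np.array([sol.labels[name] for name in order])
    s = silhouette_samples(D.d, y, metric="precomputed")
    per = {name: float(v) for name, v in zip(order, s)}
    return SilhouetteResult(s=per, average=float(np.mean(s)))


def to_newick(dend: Dendrogram) -> str:
    """Dendrogram as a Newick string; branch lengths are height
    differences between a node and its parent (leaves hang from their
    first merge)."""
    tree = hierarchy.to_tree(dend.merges)
    labels = dend.labels

    def walk(node, parent_height: float) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height - 0.0:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{parent_height - node.dist:.6g}"

    root = walk(tree, tree.dist)
    # strip the root's zero-length branch
    return root.rsplit(":", 1)[0] + ";"
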