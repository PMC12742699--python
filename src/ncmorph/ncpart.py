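"""Nest-centroid clustering and partitioning.

Species hypotheses are formed without labels: nest centroids (per-colony mean
character vectors) are clustered hierarchically with Ward's minimum-variance
criterion, and two partitioning routes -- cutting the Ward tree ("hclust") and
restarted k-means ("kmeans") -- each estimate a cluster number and assign
nests. The cluster number is accepted where the mean silhouette width over
k = 2..k_max peaks above a threshold; below it the data are declared a single
group. Nests on which the two routes disagree (under optimal cluster-label
matching) are "wild cards", deferred to the confirmative discriminant stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score


@dataclass
class PartitionConfig:
    """Knobs of the partitioning stage.

    ``silhouette_threshold`` is the acceptance level for the best mean
    silhouette width: 0.50 is the conventional boundary between "weak" and
    "reasonable" cluster structure. ``distance`` selects the variable
    representation: raw character values in micrometres (default) or
    per-variable z-scores. The gap statistic is available as an alternative
    cluster-number criterion.
    """

    k_max: int = 6
    silhouette_threshold: float = 0.50
    distance: str = "euclidean_raw"  # or "euclidean_zscore"
    kmeans_restarts: int = 100
    seed: int = 0
    criterion: str = "silhouette"  # or "gap"
    gap_n_reference: int = 50

    def __post_init__(self):
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")
        if not 0 < self.silhouette_threshold < 1:
            raise ValueError("silhouette_threshold must lie in (0, 1)")
        if self.distance not in ("euclidean_raw", "euclidean_zscore"):
            raise ValueError(f"unknown distance {self.distance!r}")


@dataclass
class Dendrogram:
    """Ward merge tree over nests: scipy linkage matrix + leaf identifiers."""

    linkage: np.ndarray
    nest_ids: list

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, k, criterion="maxclust") - 1
        return pd.Series(labels, index=self.nest_ids, name="cluster")

    def to_newick(self) -> str:
        """Newick string with nest IDs as leaves and merge heights as depths.

        Branch lengths are differences between a node's merge height and its
        parent's, so root-to-leaf path lengths equal the root merge height.
        """
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                name = str(self.nest_ids[node.id]).replace(",", "_").replace(":", "_")
                name = name.replace("(", "_").replace(")", "_").replace(";", "_")
                return f"{name}:{length:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return walk(tree, tree.dist) + ";"

    def merges_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.linkage,
                            columns=["child_a", "child_b", "height", "n_leaves"])


@dataclass
class KEstimate:
    k: int
    profile: pd.DataFrame  # columns: k, score (mean silhouette or gap)
    method: str
    criterion: str = "silhouette"


@dataclass
class PartitionSet:
    """Joint result of the two partitioning routes over the same nests."""

    k_hclust: int
    k_kmeans: int
    labels_hclust: pd.Series
    labels_kmeans: pd.Series
    concordant: pd.Series = field(default=None)
    wildcards: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "labels_hclust": self.labels_hclust,
            "labels_kmeans": self.labels_kmeans,
            "concordant": self.concordant,
            "wildcard": self.concordant.index.isin(self.wildcards),
        })


def _as_matrix(centroids: pd.DataFrame, config: PartitionConfig) -> np.ndarray:
    X = np.asarray(centroids, dtype=float)
    if np.isnan(X).any():
        raise ValueError("centroid matrix contains missing values")
    if config.distance == "euclidean_zscore":
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant variable cannot be z-scored")
        X = (X - X.mean(axis=0)) / sd
    return X


def ward_tree(centroids: pd.DataFrame, config: PartitionConfig | None = None) -> Dendrogram:
    """Ward minimum-variance agglomeration of nest centroids.

    ``centroids`` is a nests x variables DataFrame indexed by nest ID.
    """
    config = config or PartitionConfig()
    ids = list(centroids.index)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate nest IDs")
    if len(ids) < 2:
        raise ValueError("need at least 2 nests")
    X = _as_matrix(centroids, config)
    Z = hierarchy.linkage(X, method="ward")
    return Dendrogram(linkage=Z, nest_ids=ids)


def partition(centroids: pd.DataFrame, method: str, k: int,
              config: PartitionConfig | None = None) -> pd.Series:
    """Assign nests to ``k`` clusters by tree cut ("hclust") or k-means."""
    config = config or PartitionConfig()
    n = len(centroids)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of nests {n}")
    if k == 1:
        return pd.Series(0, index=centroids.index, name="cluster")
    if method == "hclust":
        return ward_tree(centroids, config).cut(k)
    if method == "kmeans":
        X = _as_matrix(centroids, config)
        km = KMeans(n_clusters=k, n_init=config.kmeans_restarts,
                    random_state=config.seed).fit(X)
        return pd.Series(km.labels_, index=centroids.index, name="cluster")
    raise ValueError(f"unknown method {method!r}")


def estimate_k(centroids: pd.DataFrame, method: str,
               config: PartitionConfig | None = None) -> KEstimate:
    """Estimate the cluster count for one partitioning route.

    Silhouette criterion (default): compute partitions for k = 2..k_max and
    their mean silhouette widths; return the maximising k if the maximum
    reaches the threshold, else k = 1 (no acceptable structure). The full
    (k, score) profile is returned for audit.
    """
    config = config or PartitionConfig()
    if len(centroids) < config.k_max:
        raise ValueError("need at least k_max nests")
    if config.criterion == "gap":
        return _estimate_k_gap(centroids, method, config)
    X = _as_matrix(centroids, config)
    rows = []
    for k in range(2, config.k_max + 1):
        labels = partition(centroids, method, k, config)
        score = float(silhouette_score(X, labels.values, metric="euclidean"))
        rows.append({"k": k, "score": score})
    profile = pd.DataFrame(rows)
    best = profile.loc[profile["score"].idxmax()]
    k_hat = int(best["k"]) if best["score"] >= config.silhouette_threshold else 1
    return KEstimate(k=k_hat, profile=profile, method=method, criterion="silhouette")


def _estimate_k_gap(centroids: pd.DataFrame, method: str,
                    config: PartitionConfig) -> KEstimate:
    """Gap statistic (uniform bounding-box reference); first-local-rise rule."""
    X = _as_matrix(centroids, config)
    rng = np.random.default_rng(config.seed)
    lo, hi = X.min(axis=0), X.max(axis=0)

    def log_wk(data, k):
        if k == 1:
            centre = data.mean(axis=0)
            return np.log(((data - centre) ** 2).sum())
        frame = pd.DataFrame(data)
        labels = partition(frame, method, k, config).values
        w = 0.0
        for c in np.unique(labels):
            pts = data[labels == c]
            w += ((pts - pts.mean(axis=0)) ** 2).sum()
        return np.log(w)

    ks = list(range(1, config.k_max + 1))
    gaps, sks = [], []
    for k in ks:
        obs = log_wk(X, k)
        ref = np.array([
            log_wk(rng.uniform(lo, hi, size=X.shape), k)
            for _ in range(config.gap_n_reference)
        ])
        gaps.append(ref.mean() - obs)
        sks.append(ref.std(ddof=1) * np.sqrt(1 + 1 / config.gap_n_reference))
    profile = pd.DataFrame({"k": ks, "score": gaps, "sk": sks})
    k_hat = ks[-1]
    for i in range(len(ks) - 1):
        if gaps[i] >= gaps[i + 1] - sks[i + 1]:
            k_hat = ks[i]
            break
    return KEstimate(k=k_hat, profile=profile, method=method, criterion="gap")


def concordance(labels_a: pd.Series, labels_b: pd.Series):
    """Compare two partitions of the same nests under optimal label matching.

    Cluster labels are arbitrary, so the a-clusters are matched one-to-one to
    b-clusters by maximising total agreement (Hungarian assignment on the
    contingency table). Returns ``(concordant, wildcards)``: a boolean Series
    and the list of nests whose matched labels disagree. Nests in clusters
    left unmatched (when the two routes found different cluster counts) are
    wild cards as well.
    """
    if set(labels_a.index) != set(labels_b.index):
        raise ValueError("partitions cover different nest sets")
    labels_b = labels_b.reindex(labels_a.index)
    cats_a = np.unique(labels_a.values)
    cats_b = np.unique(labels_b.values)
    table = np.zeros((len(cats_a), len(cats_b)))
    for i, ca in enumerate(cats_a):
        for j, cb in enumerate(cats_b):
            table[i, j] = np.sum((labels_a.values == ca) & (labels_b.values == cb))
    rows, cols = linear_sum_assignment(-table)
    mapping = {cats_a[i]: cats_b[j] for i, j in zip(rows, cols)}
    matched = labels_a.map(mapping)
    concordant = (matched == labels_b) & matched.notna()
    wildcards = list(labels_a.index[~concordant])
    return concordant.rename("concordant"), wildcards


def run_partitioning(centroids: pd.DataFrame,
                     config: PartitionConfig | None = None) -> PartitionSet:
    """Both partitioning routes end to end: estimate k, assign, compare."""
    config = config or PartitionConfig()
    est_h = estimate_k(centroids, "hclust", config)
    est_k = estimate_k(centroids, "kmeans", config)
    labels_h = partition(centroids, "hclust", est_h.k, config)
    labels_k = partition(centroids, "kmeans", est_k.k, config)
    concordant, wildcards = concordance(labels_h, labels_k)
    return PartitionSet(k_hclust=est_h.k, k_kmeans=est_k.k,
                        labels_hclust=labels_h, labels_kmeans=labels_k,
                        concordant=concordant, wildcards=wildcards)
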