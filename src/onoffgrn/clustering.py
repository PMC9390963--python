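"""Time-course profile construction and fuzzy c-means clustering.

Per (model, response) arm, replicate samples are averaged into a gene ×
timepoint profile matrix, z-normalised per gene, and soft-clustered with
fuzzy c-means (FCM). FCM alternates membership updates
``u_gc ∝ (1/d²(g,c))^(1/(m−1))`` with weighted centroid updates
``c = Σ u^m x / Σ u^m`` until the objective ``J = Σ u^m d²`` stops
improving. The fuzzifier ``m`` defaults to the Schwämmle–Jensen estimate
from the data dimensions, matching common FCM practice for short time
courses. Cluster *trends* from two tumour models are then matched by
Pearson correlation of their centroid profiles, and matched clusters'
hard-assigned gene sets intersected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import kmeans_plusplus

from onoffgrn.containers import as_frame

__all__ = [
    "ProfileMatrix",
    "FuzzyClustering",
    "ClusterMatch",
    "FuzzyCMeans",
    "average_replicates",
    "znormalize",
    "fuzzy_cmeans",
    "log_transform",
    "match_clusters",
    "overlap_genes",
    "hard_assignments",
    "schwammle_jensen_m",
]


@dataclass
class ProfileMatrix:
    """Gene × timepoint profiles for one (model, response) arm."""

    values: pd.DataFrame  # genes × timepoints (columns are day offsets)
    arm: tuple[str, str]  # (model, response)
    layer: str = "mean"  # mean | zscore
    constant_genes: frozenset = frozenset()

    @property
    def timepoints(self) -> list:
        return list(self.values.columns)


@dataclass
class FuzzyClustering:
    """FCM result: soft memberships plus per-cluster centroid profiles."""

    k: int
    m: float
    centroids: pd.DataFrame  # k × timepoints
    membership: pd.DataFrame  # genes × k
    objective: float
    seed: int | None
    n_iter: int

    def __post_init__(self) -> None:
        u = self.membership.to_numpy()
        if u.min() < -1e-12 or u.max() > 1 + 1e-12:
            raise ValueError("membership entries outside [0, 1]")
        if np.abs(u.sum(axis=1) - 1).max() > 1e-8:
            raise ValueError("membership rows must sum to 1")
        if not np.isfinite(self.centroids.to_numpy()).all():
            raise ValueError("non-finite centroid")


@dataclass(frozen=True)
class ClusterMatch:
    cluster_a: int
    cluster_b: int
    pearson_r: float


def average_replicates(matrix, meta: pd.DataFrame, model: str, response: str) -> ProfileMatrix:
    """Mean profile over the arm's replicates at each timepoint.

    ``meta`` needs columns sample_id, model, timepoint_day, response. Every
    timepoint present anywhere in ``meta`` must have at least one sample in
    the requested arm.
    """
    frame = as_frame(matrix)
    required = {"sample_id", "model", "timepoint_day", "response"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata needs columns {sorted(required)}")
    arm_meta = meta[(meta["model"] == model) & (meta["response"] == response)]
    if arm_meta.empty:
        raise ValueError(f"no samples for arm ({model}, {response})")
    all_tps = sorted(meta["timepoint_day"].unique())
    cols = {}
    for tp in all_tps:
        ids = arm_meta.loc[arm_meta["timepoint_day"] == tp, "sample_id"].tolist()
        if not ids:
            raise ValueError(f"arm ({model}, {response}) has no sample at timepoint {tp}")
        cols[tp] = frame[ids].mean(axis=1)
    values = pd.DataFrame(cols)
    values.columns.name = "timepoint_day"
    return ProfileMatrix(values=values, arm=(model, response), layer="mean")


def log_transform(profiles: ProfileMatrix, pseudocount: float = 1.0) -> ProfileMatrix:
    """log2(x + pseudocount) on a mean-layer profile matrix.

    Clustering standardised log expression (rather than raw counts) is the
    field norm for time-course profiles: it stops high-count genes and
    strong regulatory coupling from distorting profile *shape*, since
    z-scoring then absorbs any multiplicative (power-law) coupling between
    a target and its regulators.
    """
    if profiles.layer != "mean":
        raise ValueError(f"expected layer 'mean', got {profiles.layer!r}")
    return ProfileMatrix(
        values=np.log2(profiles.values + pseudocount), arm=profiles.arm, layer="mean"
    )


def znormalize(profiles: ProfileMatrix) -> ProfileMatrix:
    """Per-gene standardisation across timepoints (sd with denominator n−1).

    Constant rows become all-zero and are flagged in ``constant_genes``.
    """
    if profiles.layer != "mean":
        raise ValueError(f"expected layer 'mean', got {profiles.layer!r}")
    mat = profiles.values.to_numpy(dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    z = (mat - mean) / sd
    z[constant] = 0.0
    flagged = frozenset(profiles.values.index[constant])
    return ProfileMatrix(
        values=pd.DataFrame(z, index=profiles.values.index, columns=profiles.values.columns),
        arm=profiles.arm,
        layer="zscore",
        constant_genes=flagged,
    )


def schwammle_jensen_m(n_genes: int, n_dims: int) -> float:
    """Fuzzifier estimate from data shape (Schwämmle & Jensen rule)."""
    N, D = float(n_genes), float(n_dims)
    return float(
        1.0
        + (1418.0 / N + 22.05) * D**-2
        + (12.33 / N + 0.243) * D ** (-0.0406 * np.log(N) - 0.1134)
    )


class FuzzyCMeans(BaseEstimator, ClusterMixin):
    """Fuzzy c-means with k-means++ seeding and best-of-``n_init`` restarts.

    Parameters
    ----------
    n_clusters : int, default 6
    m : float or None
        Fuzzifier (> 1). None → Schwämmle–Jensen estimate from the data.
    tol : float
        Stop when the objective improves by less than this.
    max_iter : int
    n_init : int
        Independent k-means++ seedings; the run with the lowest final
        objective wins.
    random_state : int or None

    Attributes (after ``fit``)
    --------------------------
    cluster_centers_ : ndarray (n_clusters, n_features)
    membership_ : ndarray (n_samples, n_clusters), rows sum to 1
    objective_ : float — final weighted within-cluster SSE Σ u^m d²
    n_iter_ : int — iterations of the winning restart
    m_ : float — fuzzifier actually used
    """

    def __init__(self, n_clusters: int = 6, m: float | None = None, tol: float = 1e-9,
                 max_iter: int = 300, n_init: int = 10, random_state: int | None = 17):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.random_state = random_state

    @staticmethod
    def _memberships(X: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 1e-300
        with np.errstate(divide="ignore"):
            inv = d2 ** (-1.0 / (m - 1.0))
        u = np.where(zero.any(axis=1, keepdims=True), zero.astype(float), inv)
        return u / u.sum(axis=1, keepdims=True)

    @staticmethod
    def _objective(X: np.ndarray, centers: np.ndarray, u: np.ndarray, m: float) -> float:
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        return float((u**m * d2).sum())

    def fit(self, X, y=None):
        X = np.asarray(as_frame(X) if isinstance(X, pd.DataFrame) else X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, _ = X.shape
        k = self.n_clusters
        if k < 2:
            raise ValueError("n_clusters must be >= 2")
        n_distinct = np.unique(X, axis=0).shape[0]
        if n_distinct < k:
            raise ValueError(f"only {n_distinct} distinct profiles for k={k}")
        m = self.m if self.m is not None else schwammle_jensen_m(n, X.shape[1])
        if m <= 1:
            raise ValueError("fuzzifier m must be > 1")

        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_init):
            seed = int(rng.integers(0, 2**31 - 1))
            centers, _idx = kmeans_plusplus(X, n_clusters=k, random_state=seed)
            prev = np.inf
            for it in range(1, self.max_iter + 1):
                u = self._memberships(X, centers, m)
                um = u**m
                centers = (um.T @ X) / um.sum(axis=0)[:, None]
                obj = self._objective(X, centers, u, m)
                if prev - obj < self.tol:
                    break
                prev = obj
            u = self._memberships(X, centers, m)
            obj = self._objective(X, centers, u, m)
            if best is None or obj < best[0]:
                best = (obj, centers, u, it)

        self.objective_, self.cluster_centers_, self.membership_, self.n_iter_ = best
        self.m_ = m
        self.labels_ = self.membership_.argmax(axis=1)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def fuzzy_cmeans(
    profiles: ProfileMatrix,
    k: int = 6,
    m: float | None = None,
    tol: float = 1e-9,
    max_iter: int = 300,
    seed: int | None = 17,
    n_init: int = 10,
) -> FuzzyClustering:
    """FCM on z-scored profiles; flagged constant (all-zero) rows are excluded."""
    if profiles.layer != "zscore":
        raise ValueError("fuzzy_cmeans expects a zscore-layer ProfileMatrix")
    values = profiles.values
    if profiles.constant_genes:
        warnings.warn(
            f"excluding {len(profiles.constant_genes)} constant (all-zero) profiles from clustering",
            stacklevel=2,
        )
        values = values.drop(index=list(profiles.constant_genes))
    est = FuzzyCMeans(n_clusters=k, m=m, tol=tol, max_iter=max_iter, n_init=n_init, random_state=seed)
    est.fit(values.to_numpy(dtype=float))
    return FuzzyClustering(
        k=k,
        m=est.m_,
        centroids=pd.DataFrame(est.cluster_centers_, columns=values.columns),
        membership=pd.DataFrame(est.membership_, index=values.index),
        objective=est.objective_,
        seed=seed,
        n_iter=est.n_iter_,
    )


def match_clusters(a: FuzzyClustering, b: FuzzyClustering, r_min: float = 0.8) -> list[ClusterMatch]:
    """Cluster pairs whose centroid trends correlate at Pearson r ≥ r_min.

    Sorted by r descending (ties by cluster ids); constant centroids are
    skipped with a warning. ``match_clusters(b, a)`` yields the mirrored
    pairs.
    """
    ca, cb = a.centroids.to_numpy(dtype=float), b.centroids.to_numpy(dtype=float)
    if ca.shape[1] != cb.shape[1]:
        raise ValueError("centroid timepoint counts differ")
    out = []
    for i in range(ca.shape[0]):
        for j in range(cb.shape[0]):
            if ca[i].std() == 0 or cb[j].std() == 0:
                warnings.warn(f"constant centroid in pair ({i}, {j}); skipped", stacklevel=2)
                continue
            r = float(np.corrcoef(ca[i], cb[j])[0, 1])
            if r >= r_min:
                out.append(ClusterMatch(i, j, r))
    return sorted(out, key=lambda mch: (-mch.pearson_r, mch.cluster_a, mch.cluster_b))


def hard_assignments(clustering: FuzzyClustering) -> pd.Series:
    """Gene → cluster by argmax membership (ties to the lowest cluster index)."""
    return clustering.membership.idxmax(axis=1)


def overlap_genes(a: FuzzyClustering, cluster_a: int, b: FuzzyClustering, cluster_b: int) -> set[str]:
    """Genes hard-assigned to both matched clusters."""
    in_a = set(hard_assignments(a)[lambda s: s == cluster_a].index)
    in_b = set(hard_assignments(b)[lambda s: s == cluster_b].index)
    return in_a & in_b
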