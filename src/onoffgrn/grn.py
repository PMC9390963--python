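"""Tree-ensemble gene-regulatory-network inference.

For every target gene, its expression (standardised to unit variance) is
regressed on the candidate regulators with a random forest; the importance
of a regulator→target edge is the total impurity (variance) reduction
attributed to the regulator, summed per tree and averaged over trees — the
convention of the original tree-ensemble GRN method. No further
normalisation is applied across targets beyond the unit-variance
standardisation of each target, so importances are comparable across the
network and regulators can be ranked by their summed outgoing importance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestRegressor

from onoffgrn.containers import as_frame

__all__ = ["TreeEnsembleGRN", "ImportanceNetwork", "infer_network", "rank_regulators", "group_regulator_profiles"]


@dataclass
class ImportanceNetwork:
    """Directed weighted regulator→target edges with provenance.

    ``edges`` holds every candidate pair (zero importances included) so
    that downstream pruning sees the complete candidate graph; threshold at
    read time if a sparse view is wanted.
    """

    edges: pd.DataFrame  # columns: regulator, target, importance
    candidate_regulators: tuple[str, ...]
    n_trees: int
    k_mode: object
    seed: int | None

    def __post_init__(self) -> None:
        if (self.edges["regulator"] == self.edges["target"]).any():
            raise ValueError("self-edges are not allowed")
        if (self.edges["importance"] < 0).any():
            raise ValueError("importances must be >= 0")


def _max_features(k_mode, n_features: int):
    if k_mode == "sqrt":
        return "sqrt"
    if k_mode == "all":
        return 1.0
    if isinstance(k_mode, int):
        return min(k_mode, n_features)
    if isinstance(k_mode, str) and k_mode.startswith("fixed:"):
        return min(int(k_mode.split(":", 1)[1]), n_features)
    raise ValueError(f"unknown k_mode {k_mode!r}")


def _fit_target(X: np.ndarray, y: np.ndarray, feat_idx: np.ndarray, n_trees: int, k_mode, seed: int, bootstrap: bool):
    """Importances of ``feat_idx`` columns for one standardised target."""
    sd = y.std(ddof=1)
    if sd == 0:
        return np.zeros(feat_idx.size), True
    yn = (y - y.mean()) / sd
    rf = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=_max_features(k_mode, feat_idx.size),
        random_state=seed,
        bootstrap=bootstrap,
        n_jobs=1,
    )
    rf.fit(X[:, feat_idx], yn)
    imp = np.zeros(feat_idx.size)
    for est in rf.estimators_:
        imp += est.tree_.compute_feature_importances(normalize=False)
    return imp / len(rf.estimators_), False


class TreeEnsembleGRN(BaseEstimator):
    """Random-forest network inference as a scikit-learn style estimator.

    Parameters
    ----------
    n_trees : int, default 1000
        Trees per target-gene forest.
    k_mode : {"sqrt", "all"} or int, default "sqrt"
        Candidate features considered at each split.
    random_state : int or None
        Seeds one stream per target via ``SeedSequence.spawn``, so results
        are identical whether targets are fitted sequentially or in
        parallel.
    n_jobs : int, default 1
        Parallel target fits (results independent of n_jobs).

    Attributes
    ----------
    importances_ : pandas.DataFrame of shape (n_regulators, n_genes)
        Edge importances, regulators × targets; diagonal entries are NaN-free
        zeros only in the long form — self-pairs are omitted from ``network_``.
    network_ : pandas.DataFrame
        Long form with columns ``regulator``, ``target``, ``importance``.
    """

    def __init__(self, n_trees: int = 1000, k_mode="sqrt", random_state: int | None = None,
                 n_jobs: int = 1, bootstrap: bool = True):
        self.n_trees = n_trees
        self.k_mode = k_mode
        self.random_state = random_state
        self.n_jobs = n_jobs
        # bootstrap=False gives each tree all rows (sample-order invariant up
        # to float summation order); True is the classic bagged forest.
        self.bootstrap = bootstrap

    def fit(self, X, y=None, *, gene_names: Sequence[str] | None = None, regulators: Sequence[str] | None = None):
        """Fit per-target forests on a samples × genes matrix."""
        if isinstance(X, pd.DataFrame):
            gene_names = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            if gene_names is None:
                gene_names = [f"g{i}" for i in range(Xa.shape[1])]
        if Xa.ndim != 2:
            raise ValueError("X must be 2-D (samples × genes)")
        if Xa.shape[0] < 5:
            raise ValueError(f"need >= 5 samples, got {Xa.shape[0]}")
        genes = list(gene_names)
        if regulators is None:
            regulators = genes
        regulators = list(regulators)
        missing = set(regulators) - set(genes)
        if missing:
            raise ValueError(f"regulators not in gene set: {sorted(missing)}")

        gene_pos = {g: i for i, g in enumerate(genes)}
        reg_idx = np.array([gene_pos[r] for r in regulators])
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(self.random_state).spawn(len(genes))]

        def one(j: int):
            feat = reg_idx[reg_idx != j]
            if feat.size < 2:
                return j, feat, None  # skipped target
            imp, constant = _fit_target(Xa, Xa[:, j], feat, self.n_trees, self.k_mode, seeds[j], self.bootstrap)
            return j, feat, (imp, constant)

        results = Parallel(n_jobs=self.n_jobs)(delayed(one)(j) for j in range(len(genes)))

        rows = []
        n_constant = n_skipped = 0
        for j, feat, payload in results:
            if payload is None:
                n_skipped += 1
                continue
            imp, constant = payload
            n_constant += constant
            for f, w in zip(feat, imp):
                rows.append((genes[f], genes[j], float(w)))
        if n_constant:
            warnings.warn(f"{n_constant} constant targets received all-zero importances", stacklevel=2)
        if n_skipped:
            warnings.warn(f"{n_skipped} targets skipped (< 2 available regulators)", stacklevel=2)

        self.network_ = pd.DataFrame(rows, columns=["regulator", "target", "importance"])
        self.feature_names_in_ = np.asarray(genes, dtype=object)
        self.regulators_ = tuple(regulators)
        self.importances_ = (
            self.network_.pivot(index="regulator", columns="target", values="importance")
            .reindex(index=regulators, columns=genes)
            .fillna(0.0)
        )
        return self


def infer_network(
    matrix,
    regulators: Sequence[str] | None = None,
    n_trees: int = 1000,
    k_mode="sqrt",
    seed: int | None = 0,
    n_jobs: int = 1,
) -> ImportanceNetwork:
    """Infer a regulatory network from a genes × samples expression matrix.

    Thin wrapper over :class:`TreeEnsembleGRN` (which expects samples ×
    genes and therefore receives the transpose).
    """
    frame = as_frame(matrix)
    est = TreeEnsembleGRN(n_trees=n_trees, k_mode=k_mode, random_state=seed, n_jobs=n_jobs)
    est.fit(frame.T)
    if regulators is not None:
        est = est  # network restricted below
        edges = est.network_[est.network_["regulator"].isin(set(regulators))].reset_index(drop=True)
        cand = tuple(regulators)
    else:
        edges, cand = est.network_, tuple(frame.index)
    return ImportanceNetwork(edges=edges, candidate_regulators=cand, n_trees=n_trees, k_mode=k_mode, seed=seed)


def rank_regulators(net: ImportanceNetwork, top_n: int = 100) -> pd.DataFrame:
    """Regulators ranked by summed outgoing importance (ties: lexicographic)."""
    if len(net.edges) == 0:
        raise ValueError("network has no edges")
    sums = net.edges.groupby("regulator")["importance"].sum()
    ranking = (
        sums.rename("outgoing_sum")
        .reset_index()
        .rename(columns={"regulator": "gene"})
        .sort_values(["outgoing_sum", "gene"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    if top_n > len(ranking):
        warnings.warn(f"top_n={top_n} exceeds {len(ranking)} regulators; returning all", stacklevel=2)
        top_n = len(ranking)
    out = ranking.head(top_n).copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def group_regulator_profiles(ranking: pd.DataFrame, profiles: pd.DataFrame, k: int = 4, seed: int = 0) -> pd.Series:
    """k-means modules (default 4) of the ranked regulators' time profiles.

    Profiles are z-scored per gene across timepoints before clustering.
    """
    genes = list(ranking["gene"])
    missing = [g for g in genes if g not in profiles.index]
    if missing:
        raise ValueError(f"ranked genes without a profile: {missing}")
    if len(genes) < k:
        raise ValueError(f"cannot form {k} modules from {len(genes)} genes")
    mat = profiles.loc[genes].to_numpy(dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (mat - mean) / sd
    km = KMeans(n_clusters=k, n_init=50, random_state=seed)
    labels = km.fit_predict(z)
    return pd.Series(labels, index=pd.Index(genes, name="gene"), name="module")
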