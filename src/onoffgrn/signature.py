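"""Interferon-stimulated-gene signatures: assembly, fast subset, scoring.

The ISG universe is the union of the type I (α/β) and type II (γ)
interferon gene sets (GMT input); each member is classed ``alpha_beta``,
``gamma`` or ``both``. The *fast-on/off* subset is derived by k-means
(k=2) on z-scored responder time profiles: the cluster whose centroid is
higher at the designated early timepoint (day 0 for AB1, day 2 for Renca)
is flagged fast. Per-sample signature scores are the mean across signature
genes of each gene's z-score standardised across samples — the "average
expression" readout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from onoffgrn.clustering import ProfileMatrix, znormalize
from onoffgrn.containers import as_frame

__all__ = ["IsgSignature", "load_gmt", "write_gmt", "extract_fast_onoff", "score_signature"]

#: first post-baseline design timepoint index by model (day 0 / day 2)
DEFAULT_EARLY_INDEX = {"AB1": 0, "Renca": 1}


@dataclass
class IsgSignature:
    """Signature genes with interferon-class labels and fast flags."""

    classes: dict  # gene -> alpha_beta | gamma | both
    fast_flag: dict  # gene -> bool
    k: int
    seed: int | None
    early_index: int

    def __post_init__(self) -> None:
        if not set(self.fast_flag) <= set(self.classes):
            raise ValueError("fast genes must be signature genes")

    @property
    def fast_genes(self) -> frozenset:
        return frozenset(g for g, f in self.fast_flag.items() if f)

    @property
    def genes(self) -> frozenset:
        return frozenset(self.classes)


def load_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file to an ordered {set name: members} mapping.

    Duplicate members within a set are stored once with a warning; a line
    with fewer than three tab-separated fields is a parse error reported
    with its line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno} (need name, description, >=1 member)")
            name, _desc, *members = fields
            seen: list[str] = []
            dups = []
            for m in members:
                (dups if m in seen else seen).append(m)
            if dups:
                warnings.warn(f"{path}: line {lineno} set {name!r} lists duplicates {sorted(set(dups))}", stacklevel=2)
            sets[name] = seen
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def extract_fast_onoff(
    responder_profiles: ProfileMatrix,
    alpha_beta_genes: Iterable[str],
    gamma_genes: Iterable[str],
    k: int = 2,
    seed: int | None = 0,
    early_index: int | None = None,
) -> IsgSignature:
    """Split ISGs into fast-on/off vs chronic by k-means on responder profiles.

    The "fast" cluster is the one whose centroid is higher at the early
    timepoint (default: the model's entry in :data:`DEFAULT_EARLY_INDEX`,
    falling back to the first timepoint). Label-invariant by construction.
    """
    ab, gm = set(alpha_beta_genes), set(gamma_genes)
    isgs = ab | gm
    profiles = responder_profiles
    if profiles.layer == "mean":
        profiles = znormalize(profiles)
    present = [g for g in profiles.values.index if g in isgs]
    absent = sorted(isgs - set(present))
    if absent:
        warnings.warn(f"{len(absent)} ISGs absent from the profile matrix were dropped", stacklevel=2)
    if len(present) < 2 * k:
        raise ValueError(f"need at least {2 * k} ISGs with profiles, have {len(present)}")
    X = profiles.values.loc[present].to_numpy(dtype=float)
    if np.unique(X, axis=0).shape[0] < 2:
        raise ValueError("all ISG profiles identical; fast/slow clusters undefined")

    if early_index is None:
        early_index = DEFAULT_EARLY_INDEX.get(profiles.arm[0], 0)
    km = KMeans(n_clusters=k, n_init=50, random_state=seed)
    labels = km.fit_predict(X)
    fast_cluster = int(np.argmax(km.cluster_centers_[:, early_index]))

    classes = {g: ("both" if g in ab and g in gm else "alpha_beta" if g in ab else "gamma") for g in sorted(isgs)}
    fast_flag = {g: False for g in classes}
    for g, lab in zip(present, labels):
        fast_flag[g] = lab == fast_cluster
    return IsgSignature(classes=classes, fast_flag=fast_flag, k=k, seed=seed, early_index=early_index)


def score_signature(matrix, signature_genes: Iterable[str]) -> pd.Series:
    """Per-sample mean z-score over the signature genes.

    Each gene is standardised across samples (sd denominator n−1); missing
    signature genes are dropped with a warning, zero overlap is an error.
    """
    frame = as_frame(matrix)
    wanted = list(dict.fromkeys(signature_genes))
    present = [g for g in wanted if g in frame.index]
    missing = [g for g in wanted if g not in frame.index]
    if not present:
        raise ValueError(f"no signature genes found in the matrix; missing: {missing}")
    if missing:
        warnings.warn(f"{len(missing)} signature genes missing from matrix: {missing[:10]}", stacklevel=2)
    sub = frame.loc[present].to_numpy(dtype=float)
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mean) / sd
    return pd.Series(z.mean(axis=0), index=frame.columns, name="signature_score")
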