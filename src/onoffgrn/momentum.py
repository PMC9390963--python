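"""Transcriptional momentum of cells in a 2-D velocity embedding.

Momentum is the squared L2 norm of a cell's embedding-velocity vector,
‖v‖² = vx² + vy² — a rotation-invariant scalar measuring how fast the
cell's transcriptional state is moving across the embedding. Groups
(clusters, response arms) are compared with two-sided rank-sum tests and
Gaussian kernel density estimates on a shared grid.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["momentum", "compare_momentum"]


def momentum(vectors: pd.DataFrame) -> pd.Series:
    """Per-cell squared L2 norm of (vx, vy)."""
    if not {"vx", "vy"}.issubset(vectors.columns):
        raise ValueError("vectors needs columns vx, vy")
    v = vectors[["vx", "vy"]].to_numpy(dtype=float)
    bad = ~np.isfinite(v).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite velocity for cells: {list(vectors.index[bad][:5])}")
    return pd.Series((v**2).sum(axis=1), index=vectors.index, name="momentum")


def compare_momentum(momenta: pd.Series, groups: pd.Series, grid_size: int = 256, bandwidth=None) -> dict:
    """Group summaries, pairwise rank tests and KDE curves for momenta.

    Rank tests are asymptotic two-sided Mann–Whitney without continuity
    correction (so identical groups give p = 1 exactly). Densities use a
    Gaussian kernel with Scott's-rule bandwidth unless ``bandwidth`` is
    given, evaluated on a grid shared by all groups.
    """
    groups = groups.loc[momenta.index]
    names = sorted(groups.unique())
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    by_group = {g: momenta[groups == g].to_numpy(dtype=float) for g in names}
    for g, x in by_group.items():
        if x.size < 3:
            raise ValueError(f"group {g!r} has n < 3")

    summary = {
        g: {"n": int(x.size), "mean": float(x.mean()), "median": float(np.median(x))}
        for g, x in by_group.items()
    }

    tests = {}
    for ga, gb in combinations(names, 2):
        res = stats.mannwhitneyu(
            by_group[ga], by_group[gb], alternative="two-sided",
            use_continuity=False, method="asymptotic",
        )
        tests[f"{ga}|{gb}"] = {"U": float(res.statistic), "p": float(res.pvalue)}

    lo = min(x.min() for x in by_group.values())
    hi = max(x.max() for x in by_group.values())
    if hi == lo:
        hi = lo + 1.0
    grid = np.linspace(lo, hi, grid_size)
    densities = {}
    for g, x in by_group.items():
        if np.ptp(x) == 0:
            warnings.warn(f"group {g!r} has constant momenta; density degenerate, skipped", stacklevel=2)
            densities[g] = None
            continue
        kde = stats.gaussian_kde(x, bw_method=bandwidth)  # None -> Scott's rule
        densities[g] = kde(grid)
    return {"summary": summary, "tests": tests, "grid": grid, "densities": densities}
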