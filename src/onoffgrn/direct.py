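"""Promoter-window pruning of inferred networks and the hive-quadrant statistic.

An inferred importance network is over-connected: tree ensembles assign a
weight to every candidate regulator/target pair. The pruning step keeps a
TF→gene edge only when it is plausibly *direct*: the target is
differentially expressed and carries a binding site for that TF inside a
fixed promoter window around its transcription start site (400 bp upstream
/ 300 bp downstream, strand-oriented, BED half-open coordinates, any
overlap of at least 1 bp qualifies).

Downstream summaries: the TF→ISG importance matrix (absent edges are 0)
and the hive-quadrant statistic — among edges above the 0.9 importance
quantile, the fraction running from interferon-related TFs to fast-on/off
ISGs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from onoffgrn.grn import ImportanceNetwork

#: Interferon-related transcription factors forming the red hive axis.
DEFAULT_IFN_TFS = ("Irf1", "Stat1", "Stat2", "Irf7", "Irf9")

NODE_CLASSES = ("ifn_tf", "other_tf", "fast_isg", "other")

__all__ = [
    "DEFAULT_IFN_TFS",
    "DirectNetwork",
    "promoter_window",
    "prune_direct",
    "tf_to_isg_matrix",
    "hive_quadrant_stats",
]


@dataclass
class DirectNetwork:
    """Pruned TF→target edges plus hive-axis node classes and provenance."""

    edges: pd.DataFrame  # columns regulator, target, importance
    node_class: dict[str, str]
    window_up: int
    window_down: int
    strand_aware: bool
    n_dropped_no_tss: int = 0
    n_dropped_no_tfbs: int = 0


def promoter_window(
    tss_position: int, strand: str, up: int = 400, down: int = 300, *, ignore_strand: bool = False
) -> tuple[int, int]:
    """Half-open promoter interval around a TSS, clipped at 0.

    ``up`` extends 5' of the gene, ``down`` 3': a + strand gene at 10,000
    gives [9600, 10300); the same TSS on − gives [9700, 10400). With
    ``ignore_strand`` the + orientation is used for every gene.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if strand == "+" or ignore_strand:
        start, end = tss_position - up, tss_position + down
    else:
        start, end = tss_position - down, tss_position + up
    return max(start, 0), max(end, 0)


def _tss_lookup(tss: pd.DataFrame) -> dict[str, tuple[str, int, str]]:
    required = {"gene", "chrom", "tss", "strand"}
    if not required.issubset(tss.columns):
        raise ValueError(f"TSS table needs columns {sorted(required)}")
    lookup: dict[str, tuple[str, int, str]] = {}
    dup = []
    for row in tss.itertuples(index=False):
        if row.gene in lookup:
            dup.append(row.gene)
            continue  # first listed wins
        if row.tss < 0:
            raise ValueError(f"negative TSS position for {row.gene}")
        lookup[row.gene] = (row.chrom, int(row.tss), row.strand)
    if dup:
        warnings.warn(f"duplicate TSS entries ignored for {sorted(set(dup))}", stacklevel=3)
    return lookup


def _tfbs_trees(tfbs: pd.DataFrame) -> dict[tuple[str, str], IntervalTree]:
    required = {"tf", "chrom", "start", "end"}
    if not required.issubset(tfbs.columns):
        raise ValueError(f"TFBS table needs columns {sorted(required)}")
    trees: dict[tuple[str, str], IntervalTree] = {}
    for row in tfbs.itertuples(index=False):
        if row.start >= row.end:
            raise ValueError(f"empty TFBS interval for {row.tf}: [{row.start}, {row.end})")
        trees.setdefault((row.tf, row.chrom), IntervalTree()).addi(int(row.start), int(row.end))
    return trees


def classify_nodes(
    genes: Iterable[str],
    tf_list: Iterable[str],
    ifn_tfs: Iterable[str] = DEFAULT_IFN_TFS,
    fast_isgs: Iterable[str] = (),
) -> dict[str, str]:
    """Assign each gene to one hive axis (TF classes take precedence)."""
    tfs = set(tf_list)
    ifn = set(ifn_tfs) & tfs
    fast = set(fast_isgs)
    out = {}
    for g in genes:
        if g in ifn:
            out[g] = "ifn_tf"
        elif g in tfs:
            out[g] = "other_tf"
        elif g in fast:
            out[g] = "fast_isg"
        else:
            out[g] = "other"
    return out


def prune_direct(
    net: ImportanceNetwork,
    tss: pd.DataFrame,
    tfbs: pd.DataFrame,
    de_genes: Iterable[str],
    tf_list: Iterable[str],
    up: int = 400,
    down: int = 300,
    *,
    ignore_strand: bool = False,
    ifn_tfs: Iterable[str] = DEFAULT_IFN_TFS,
    fast_isgs: Iterable[str] = (),
) -> DirectNetwork:
    """Retain edges with a same-TF binding site in the target's promoter window.

    An edge (r, t) survives iff r is in ``tf_list``, t is differentially
    expressed, and at least one TFBS of r on t's chromosome overlaps t's
    promoter window by ≥ 1 bp. Targets without a TSS record and TFs without
    any binding site are dropped with a counted warning. Output order
    follows the input edge order restricted to retained edges; the decision
    itself is order-independent.
    """
    de = set(de_genes)
    tfs = set(tf_list)
    lookup = _tss_lookup(tss)
    trees = _tfbs_trees(tfbs)
    tfs_with_sites = {tf for (tf, _chrom) in trees}

    no_tss: set[str] = set()
    no_tfbs: set[str] = set()
    keep_rows = []
    for row in net.edges.itertuples(index=False):
        r, t = row.regulator, row.target
        if r not in tfs or t not in de:
            continue
        if r not in tfs_with_sites:
            no_tfbs.add(r)
            continue
        if t not in lookup:
            no_tss.add(t)
            continue
        chrom, pos, strand = lookup[t]
        start, end = promoter_window(pos, strand, up, down, ignore_strand=ignore_strand)
        tree = trees.get((r, chrom))
        if tree is not None and start < end and tree.overlap(start, end):
            keep_rows.append((r, t, row.importance))

    if no_tss:
        warnings.warn(f"{len(no_tss)} DE targets lacked a TSS record; their edges dropped", stacklevel=2)
    if no_tfbs:
        warnings.warn(f"TFs with no binding site anywhere: {sorted(no_tfbs)}; edges dropped", stacklevel=2)

    edges = pd.DataFrame(keep_rows, columns=["regulator", "target", "importance"])
    nodes = set(edges["regulator"]) | set(edges["target"])
    return DirectNetwork(
        edges=edges,
        node_class=classify_nodes(sorted(nodes), tfs, ifn_tfs, fast_isgs),
        window_up=up,
        window_down=down,
        strand_aware=not ignore_strand,
        n_dropped_no_tss=len(no_tss),
        n_dropped_no_tfbs=len(no_tfbs),
    )


def tf_to_isg_matrix(direct: DirectNetwork, tfs: Iterable[str], isgs: Iterable[str]) -> pd.DataFrame:
    """TF × ISG importance matrix; pairs without a retained edge are 0."""
    tfs = list(tfs)
    isgs = list(isgs)
    mat = pd.DataFrame(0.0, index=pd.Index(tfs, name="tf"), columns=pd.Index(isgs, name="isg"))
    sub = direct.edges[direct.edges["regulator"].isin(tfs) & direct.edges["target"].isin(isgs)]
    for row in sub.itertuples(index=False):
        mat.loc[row.regulator, row.target] = row.importance
    return mat


def hive_quadrant_stats(direct: DirectNetwork, quantile: float = 0.9) -> dict:
    """Share of top-quantile edges in the IFN-TF → fast-ISG quadrant.

    The threshold is the linear-interpolation empirical quantile of edge
    importances; "top" edges exceed it strictly. The fraction is computed
    among top edges whose source class is ``ifn_tf`` and target class is
    ``fast_isg``.
    """
    imp = direct.edges["importance"].to_numpy(dtype=float)
    if imp.size < 10:
        raise ValueError(f"need >= 10 edges for a quantile statistic, got {imp.size}")
    threshold = float(np.quantile(imp, quantile, method="linear"))
    top = direct.edges[imp > threshold]
    if len(top) == 0:
        warnings.warn("no edges strictly above the quantile threshold", stacklevel=2)
        frac = 0.0
    else:
        src = top["regulator"].map(direct.node_class)
        tgt = top["target"].map(direct.node_class)
        frac = float(((src == "ifn_tf") & (tgt == "fast_isg")).mean())
    return {
        "threshold": threshold,
        "n_top_edges": int(len(top)),
        "fraction_in_tf_to_isg_quadrant": frac,
    }
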