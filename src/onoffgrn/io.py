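"""Readers and writers for the pipeline's plain-text formats.

Matrices travel as TSV (gene ids in column 1, sample ids in the header),
annotations as BED6 (TSS: name=gene, strand used; TFBS: name=TF), gene
sets as GMT, growth curves and survival records as long-format TSV, and
configuration as YAML.
"""

from __future__ import annotations

import pandas as pd
import yaml

from onoffgrn.containers import ExpressionMatrix, as_frame
from onoffgrn.outcomes import GrowthCurve

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "write_tss_bed",
    "read_tss_bed",
    "write_tfbs_bed",
    "read_tfbs_bed",
    "read_growth_curves",
    "write_growth_curves",
    "load_config",
]


def read_matrix(path, layer: str = "counts") -> ExpressionMatrix:
    """Read a genes × samples TSV; non-numeric cells are located and reported."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids {dup}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dup}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            row = bad[0] if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric value at (row {row!r}, column {col!r})")
    return ExpressionMatrix(df.astype(float), layer=layer)


def write_matrix(matrix, path) -> None:
    as_frame(matrix).to_csv(path, sep="\t", index_label="gene")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    required = {"sample_id", "model", "timepoint_day", "response"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: metadata lacks columns {sorted(missing)}")
    return meta


_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def write_tss_bed(tss: pd.DataFrame, path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": tss["chrom"],
            "start": tss["tss"].astype(int),
            "end": tss["tss"].astype(int) + 1,
            "name": tss["gene"],
            "score": 0,
            "strand": tss["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_tss_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, names=_BED_COLS)
    return pd.DataFrame(
        {"gene": bed["name"], "chrom": bed["chrom"], "tss": bed["start"].astype(int), "strand": bed["strand"]}
    )


def write_tfbs_bed(tfbs: pd.DataFrame, path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": tfbs["chrom"],
            "start": tfbs["start"].astype(int),
            "end": tfbs["end"].astype(int),
            "name": tfbs["tf"],
            "score": 0,
            "strand": ".",
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_tfbs_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, names=_BED_COLS)
    return pd.DataFrame(
        {"tf": bed["name"], "chrom": bed["chrom"], "start": bed["start"].astype(int), "end": bed["end"].astype(int)}
    )


def write_growth_curves(curves, path) -> None:
    rows = []
    for c in curves:
        for d, a in zip(c.days, c.areas_mm2):
            rows.append({"mouse_id": c.mouse_id, "cage_id": c.cage_id, "day": d, "area_mm2": a})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_growth_curves(path) -> list[GrowthCurve]:
    df = pd.read_csv(path, sep="\t")
    curves = []
    for (mouse, cage), grp in df.groupby(["mouse_id", "cage_id"], sort=True):
        grp = grp.sort_values("day")
        curves.append(GrowthCurve(str(mouse), str(cage), grp["day"].to_numpy(), grp["area_mm2"].to_numpy()))
    return curves


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg
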