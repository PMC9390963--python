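"""Shared in-memory containers.

Expression data travel as a genes × samples :class:`pandas.DataFrame`
wrapped in :class:`ExpressionMatrix`, which carries a *layer* tag so that
stages with layer preconditions (e.g. the TPM prevalence filter) can refuse
the wrong input instead of silently mis-computing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

LAYERS = ("counts", "TPM", "zscore")


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with a layer tag.

    Parameters
    ----------
    values
        Numeric frame, rows indexed by unique gene ids, columns by unique
        sample ids. Must be non-negative unless ``layer == "zscore"``.
    layer
        One of ``"counts"``, ``"TPM"``, ``"zscore"``.
    """

    values: pd.DataFrame
    layer: str = "counts"

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        idx = self.values.index
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        cols = self.values.columns
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression matrix must be numeric")
        if self.layer != "zscore" and np.nanmin(arr, initial=0) < 0:
            raise ValueError(f"negative value in {self.layer} layer")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tpm(self) -> "ExpressionMatrix":
        """Column-normalise to one million (no length correction).

        Gene lengths are out of scope here: inputs are gene-level counts or
        already length-corrected abundances, so TPM reduces to per-sample
        scaling.
        """
        colsum = self.values.sum(axis=0)
        if (colsum <= 0).any():
            bad = colsum.index[colsum <= 0].tolist()
            raise ValueError(f"cannot TPM-normalise all-zero samples: {bad}")
        return ExpressionMatrix(self.values / colsum * 1e6, layer="TPM")

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[:, list(sample_ids)])


def as_frame(matrix) -> pd.DataFrame:
    """Accept an :class:`ExpressionMatrix` or a bare DataFrame."""
    if isinstance(matrix, ExpressionMatrix):
        return matrix.values
    if isinstance(matrix, pd.DataFrame):
        return matrix
    raise TypeError(f"expected ExpressionMatrix or DataFrame, got {type(matrix)}")
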