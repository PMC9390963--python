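"""Cytokine-signature deconvolution of bulk expression.

A reference of 7 cytokine-induced T-cell populations (IFNβ, Resting, Th17,
Th2, Th1, Th0, iTreg) is built by collapsing labelled samples to per-gene
population means. Bulk samples, TPM-normalised and filtered to genes with
TPM > 0.3 in at least 8 samples, are then decomposed as non-negative
mixtures of the reference columns.

The mixture solver is constrained non-negative least squares (NNLS) with
post-hoc sum-to-one renormalisation. This deliberately replaces the
ν-SVR of the CIBERSORT family: on exact mixtures both estimate the same
quantity and NNLS recovers it to numerical precision, with no
undocumented internals. Quantile normalisation is not applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from onoffgrn.containers import ExpressionMatrix, as_frame

__all__ = [
    "DEFAULT_POPULATIONS",
    "MixtureEstimate",
    "NNLSDeconvolver",
    "build_reference",
    "filter_genes_tpm",
    "deconvolve",
]

DEFAULT_POPULATIONS = ("IFNB", "Resting", "Th17", "Th2", "Th1", "Th0", "iTreg")


@dataclass
class MixtureEstimate:
    """Per-sample population fractions (rows sum to 1) and residual norms."""

    fractions: pd.DataFrame  # samples × populations
    residuals: pd.Series

    def __post_init__(self) -> None:
        arr = self.fractions.to_numpy()
        if (arr < -1e-12).any():
            raise ValueError("fractions must be non-negative")
        if np.abs(arr.sum(axis=1) - 1).max() > 1e-8:
            raise ValueError("fractions must sum to 1")


def build_reference(samples, population_labels: Mapping[str, str]) -> pd.DataFrame:
    """Collapse labelled samples to per-gene population means."""
    frame = as_frame(samples)
    unlabelled = [s for s in frame.columns if s not in population_labels]
    if unlabelled:
        raise ValueError(f"unlabelled samples: {unlabelled}")
    groups: dict[str, list[str]] = {}
    for s in frame.columns:
        groups.setdefault(population_labels[s], []).append(s)
    ref = pd.DataFrame({pop: frame[cols].mean(axis=1) for pop, cols in groups.items()})
    ref.columns.name = "population"
    return ref


def filter_genes_tpm(matrix: ExpressionMatrix, min_tpm: float = 0.3, min_samples: int = 8) -> ExpressionMatrix:
    """Keep genes with TPM strictly above ``min_tpm`` in ≥ ``min_samples`` samples."""
    if not isinstance(matrix, ExpressionMatrix) or matrix.layer != "TPM":
        raise ValueError("filter_genes_tpm requires an ExpressionMatrix with layer 'TPM'")
    keep = (matrix.values > min_tpm).sum(axis=1) >= min_samples
    return ExpressionMatrix(matrix.values.loc[keep], layer="TPM")


class NNLSDeconvolver(BaseEstimator, TransformerMixin):
    """Estimate reference-population fractions by non-negative least squares.

    ``fit`` stores the reference (genes × populations); ``transform``
    solves one NNLS per sample over the genes shared with the reference
    and renormalises the coefficients to fractions.
    """

    def __init__(self):
        pass

    def fit(self, reference, y=None):
        ref = as_frame(reference)
        if ref.columns.duplicated().any():
            raise ValueError("population labels must be unique")
        if (ref.to_numpy() < 0).any():
            raise ValueError("reference must be non-negative")
        if np.linalg.matrix_rank(ref.to_numpy(dtype=float)) < ref.shape[1]:
            warnings.warn("reference is rank-deficient; fractions may be non-unique", stacklevel=2)
        self.reference_ = ref
        return self

    def transform(self, X) -> MixtureEstimate:
        frame = as_frame(X)
        shared = self.reference_.index.intersection(frame.index)
        unmatched = self.reference_.index.difference(frame.index)
        if len(unmatched):
            warnings.warn(f"{len(unmatched)} reference genes absent from samples", stacklevel=2)
        if len(shared) < self.reference_.shape[1]:
            raise ValueError(
                f"only {len(shared)} shared genes for {self.reference_.shape[1]} populations"
            )
        A = self.reference_.loc[shared].to_numpy(dtype=float)
        fracs, resids = [], []
        for sample in frame.columns:
            b = frame.loc[shared, sample].to_numpy(dtype=float)
            coef, resid = nnls(A, b)
            total = coef.sum()
            frac = coef / total if total > 0 else np.full(coef.size, 1.0 / coef.size)
            fracs.append(frac)
            resids.append(resid)
        fractions = pd.DataFrame(fracs, index=frame.columns, columns=self.reference_.columns)
        return MixtureEstimate(fractions=fractions, residuals=pd.Series(resids, index=frame.columns, name="residual"))


def deconvolve(mixtures, reference) -> MixtureEstimate:
    """One-shot wrapper: fit the reference, transform the mixture samples.

    ``mixtures`` may be a single-sample Series or a genes × samples frame.
    """
    if isinstance(mixtures, pd.Series):
        mixtures = mixtures.to_frame()
    return NNLSDeconvolver().fit(reference).transform(mixtures)
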