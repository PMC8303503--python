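"""Count normalization and low-dimensional views.

Raw gene counts are quantile-normalized (every sample receives the same
reference distribution, the vector of row-wise means of the column-sorted
matrix) and then log10(x + 1) transformed. Each dataset/batch is normalized
independently; no cross-dataset normalization or batch correction is done —
batches are treated as separate datasets downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import (
    GeneExpressionMatrix,
    LOG_TRANSFORMED,
    QUANTILE_NORMALIZED,
    RAW_COUNTS,
    ValidationError,
)


@dataclass
class PCAScores:
    sample_ids: list[str]
    scores: np.ndarray  # samples x k
    explained_variance_ratio: np.ndarray  # length k, non-increasing


def quantile_normalize(matrix: GeneExpressionMatrix) -> GeneExpressionMatrix:
    """Map every sample's values onto the shared rank-mean reference.

    The reference distribution is the vector of row-wise means of the
    column-sorted matrix. Ties within a column receive the mean of the
    reference values at their tied ranks, so the operation is idempotent.
    """
    if matrix.scale != RAW_COUNTS:
        raise ValidationError(f"expected raw counts, got scale {matrix.scale!r}")
    if matrix.n_samples < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    values = matrix.values
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # average the reference over tied ranks
        _, inverse = np.unique(col, return_inverse=True)
        sums = np.bincount(inverse, weights=assigned)
        counts = np.bincount(inverse)
        out[:, j] = (sums / counts)[inverse]
    return GeneExpressionMatrix(
        gene_ids=matrix.gene_ids,
        sample_ids=matrix.sample_ids,
        values=out,
        dataset_label=matrix.dataset_label,
        scale=QUANTILE_NORMALIZED,
    )


def log_transform(matrix: GeneExpressionMatrix) -> GeneExpressionMatrix:
    """Elementwise log10(x + 1); the pseudocount keeps zeros finite."""
    if np.any(matrix.values < 0):
        raise ValidationError("log transform requires non-negative values")
    return GeneExpressionMatrix(
        gene_ids=matrix.gene_ids,
        sample_ids=matrix.sample_ids,
        values=np.log10(matrix.values + 1.0),
        dataset_label=matrix.dataset_label,
        scale=LOG_TRANSFORMED,
    )


def pca_scores(matrix, k: int) -> PCAScores:
    """Scores of samples on the top-k principal axes of gene-centered data.

    Accepts a log-transformed expression matrix or a pathway activation
    matrix (any container with ``sample_ids`` and feature x sample
    ``values``). Deterministic up to per-component sign.
    """
    from sklearn.decomposition import PCA

    values = np.asarray(matrix.values, dtype=float)
    n_features, n_samples = values.shape
    if not 1 <= k <= min(n_samples - 1, n_features):
        raise ValidationError(f"k={k} out of range for {n_features} features x {n_samples} samples")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(values.T)  # samples x k
    return PCAScores(
        sample_ids=list(matrix.sample_ids),
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
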