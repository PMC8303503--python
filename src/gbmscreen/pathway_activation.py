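"""Pathway activation levels (PAL) and the pathway-level survival screen.

A pathway activation level is a signed, role-weighted mean of member genes'
log expression ratios. Each gene's case-to-normal ratio (CNR) is its
quantile-normalized, +1-shifted expression divided by that gene's geometric
mean across all samples of the dataset; activators (+1) and repressors (-1)
contribute with opposite signs:

    PAL(p, s) = sum_g ARR(g, p) * log10 CNR(g, s) / sum_g |ARR(g, p)|

over pathway members present in the expression matrix. Positive PAL marks
pathway up-regulation relative to the dataset average, negative PAL
down-regulation. Only pathways with at least ``min_genes`` measured members
are scored (production default 10). The signed weighted-mean form is this
package's reconstruction of the pathway-activation scoring approach it
follows; the sign convention, the per-dataset geometric-mean reference and
the member-count filter are preserved properties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    GeneExpressionMatrix,
    PathwayCollection,
    QUANTILE_NORMALIZED,
    ValidationError,
)
from .survival_stats import GeneSurvivalResult, ScreenConfig, screen_features

logger = logging.getLogger(__name__)

DEFAULT_MIN_GENES = 10


@dataclass
class CNRMatrix:
    """Per-gene expression ratios to the gene's geometric-mean reference."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # genes x samples, strictly positive


@dataclass
class PALMatrix:
    """Pathways x samples activation levels (positive = up-regulated)."""

    pathway_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    @property
    def feature_ids(self) -> list[str]:
        return self.pathway_ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.pathway_ids, columns=self.sample_ids)


def case_to_normal_ratio(matrix: GeneExpressionMatrix) -> CNRMatrix:
    """CNR(g, s) = shifted value / geometric mean of gene g over all samples.

    Expects quantile-normalized counts; the +1 shift applied here makes
    every entry strictly positive so the geometric mean is always defined.
    Genes that still carry a non-positive shifted value (possible only for
    non-count inputs) are excluded with a log note.
    """
    if matrix.scale != QUANTILE_NORMALIZED:
        raise ValidationError(f"expected quantile-normalized values, got {matrix.scale!r}")
    shifted = matrix.values + 1.0
    keep = np.all(shifted > 0, axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("case_to_normal_ratio: excluded %d genes with non-positive values", n_dropped)
    shifted = shifted[keep]
    geo_mean = np.exp(np.mean(np.log(shifted), axis=1))
    return CNRMatrix(
        gene_ids=[g for g, k in zip(matrix.gene_ids, keep) if k],
        sample_ids=list(matrix.sample_ids),
        values=shifted / geo_mean[:, None],
    )


def pal_scores(
    cnr: CNRMatrix, pathways: PathwayCollection, min_genes: int = DEFAULT_MIN_GENES
) -> PALMatrix:
    """Role-weighted mean of log10 CNR over each pathway's measured members.

    Pathways with fewer than ``min_genes`` members present in the matrix,
    and pathways whose present members all carry zero role weight, are
    dropped with a log note.
    """
    log_cnr = np.log10(cnr.values)
    row_of = {g: i for i, g in enumerate(cnr.gene_ids)}
    ids: list[str] = []
    rows: list[np.ndarray] = []
    n_dropped = 0
    for p in pathways:
        present = [(row_of[g], w) for g, w in p.members.items() if g in row_of]
        weight_norm = sum(abs(w) for _, w in present)
        if len(present) < min_genes or weight_norm == 0:
            n_dropped += 1
            continue
        idx = np.asarray([i for i, _ in present])
        arr = np.asarray([w for _, w in present])
        rows.append(arr @ log_cnr[idx] / weight_norm)
        ids.append(p.pathway_id)
    if n_dropped:
        logger.info("pal_scores: dropped %d pathways below the %d-member filter", n_dropped, min_genes)
    if not ids:
        raise ValidationError("no pathway passed the member-count filter")
    return PALMatrix(pathway_ids=ids, sample_ids=list(cnr.sample_ids), values=np.vstack(rows))


def screen_pathways(pal: PALMatrix, survival, config: ScreenConfig | None = None) -> list[GeneSurvivalResult]:
    """Tertile high-vs-low survival screen applied to PAL rows.

    Same contract as the gene screen; results feed ``select_differential``
    and the consensus machinery unchanged.
    """
    return screen_features(pal, survival, config)
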