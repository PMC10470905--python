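"""Weighted receptor gene set construction from paired training data.

For each receptor (ADT antibody), every gene's reconstructed expression is
rank-correlated with the receptor's CLR-normalized ADT level across the shared
training cells. The top ``set_size`` genes with strictly positive Spearman
correlation form the receptor's weighted set; the correlations themselves are
the weights.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.stats import rankdata

from .types import GeneSetWeights, NormalizedMatrix, ReconstructedMatrix, ValidationError

__all__ = ["spearman_rho", "correlation_table", "build_gene_sets"]

logger = logging.getLogger(__name__)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of average-rank vectors.

    Returns NaN when either vector is constant (ranks have zero variance).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValidationError("need at least 2 observations")
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(((rx - rx.mean()) @ (ry - ry.mean())) / (x.size * sx * sy))


def _rank_standardize(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise average ranks, centered and scaled to unit norm.

    Returns the standardized ranks and a boolean mask of constant columns
    (left as zeros so their correlations come out 0, masked to NaN later).
    """
    ranks = rankdata(mat, axis=0)
    ranks -= ranks.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(ranks, axis=0)
    constant = norms == 0
    norms[constant] = 1.0
    return ranks / norms, constant


def correlation_table(recon_train: ReconstructedMatrix,
                      adt_train: NormalizedMatrix) -> np.ndarray:
    """Dense genes-by-receptors Spearman correlation matrix.

    Computed in one pass as a product of standardized rank matrices;
    entries involving a constant column are NaN.
    """
    if recon_train.cell_ids != adt_train.cell_ids:
        raise ValidationError("training RNA and ADT matrices must share cell ids in order")
    gr, g_const = _rank_standardize(recon_train.values)
    ar, a_const = _rank_standardize(adt_train.values)
    rho = gr.T @ ar
    rho[g_const, :] = np.nan
    rho[:, a_const] = np.nan
    return rho


def build_gene_sets(recon_train: ReconstructedMatrix, adt_train: NormalizedMatrix,
                    set_size: int = 10) -> GeneSetWeights:
    """Build the weighted membership matrix A as top-``set_size`` truncation.

    Per receptor, keeps the ``set_size`` genes with the largest strictly
    positive correlation (fewer if fewer are positive); ties at the cutoff
    break lexicographically on gene id for reproducibility. A receptor with no
    positively correlated gene (e.g. a constant antibody) is recorded as an
    empty set with a warning and skipped downstream.
    """
    if set_size < 1:
        raise ValidationError("set_size must be >= 1")
    rho = correlation_table(recon_train, adt_train)
    genes = np.asarray(recon_train.feature_ids)
    sets: dict[str, list[tuple[str, float]]] = {}
    for j, receptor in enumerate(adt_train.feature_ids):
        col = rho[:, j]
        pos = np.flatnonzero(col > 0)  # NaN compares false
        if pos.size == 0:
            logger.warning("receptor %s: no positively correlated genes; empty set", receptor)
            sets[receptor] = []
            continue
        # sort by decreasing rho, then gene id ascending
        order = pos[np.lexsort((genes[pos], -col[pos]))]
        top = order[:set_size]
        sets[receptor] = [(str(genes[i]), float(col[i])) for i in top]
    return GeneSetWeights(sets, set_size_requested=set_size,
                          gene_universe=list(recon_train.feature_ids))
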