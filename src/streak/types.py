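"""Core in-memory containers shared across the pipeline.

All matrices are oriented cells-by-features. 10x-style MatrixMarket
triplets on disk are features-by-cells and are transposed on load by
:mod:`streak.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "ReconstructedMatrix",
    "RankSelection",
    "GeneSetWeights",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


def _check_ids(ids: list[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")
    return ids


@dataclass
class CountMatrix:
    """Raw cell-by-feature non-negative counts (RNA genes or ADT antibodies).

    Parameters
    ----------
    values
        ``(n_cells, n_features)`` array of non-negative counts.
    cell_ids, feature_ids
        Unique string identifiers for rows and columns.
    modality
        ``"rna"`` or ``"adt"``.
    """

    values: np.ndarray
    cell_ids: list[str]
    feature_ids: list[str]
    modality: str = "rna"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        self.cell_ids = _check_ids(list(self.cell_ids), "cell ids")
        self.feature_ids = _check_ids(list(self.feature_ids), "feature ids")
        if self.values.shape != (len(self.cell_ids), len(self.feature_ids)):
            raise ValidationError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.cell_ids)} cells x {len(self.feature_ids)} features"
            )
        if self.modality not in ("rna", "adt"):
            raise ValidationError(f"modality must be 'rna' or 'adt', got {self.modality!r}")
        if np.any(self.values < 0):
            raise ValidationError("counts must be non-negative")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("counts must be finite")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, cell_ids: list[str]) -> "CountMatrix":
        """Return a new matrix restricted to ``cell_ids`` (in that order)."""
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in pos]
        if missing:
            raise ValidationError(f"unknown cell ids: {missing[:5]}")
        idx = [pos[c] for c in cell_ids]
        return CountMatrix(
            self.values[idx, :], list(cell_ids), list(self.feature_ids), self.modality
        )


@dataclass
class NormalizedMatrix:
    """Normalized expression values; ``normalization`` is ``lognorm`` or ``clr``."""

    values: np.ndarray
    cell_ids: list[str]
    feature_ids: list[str]
    normalization: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("normalized values must be finite")
        if self.normalization == "lognorm" and np.any(self.values < 0):
            raise ValidationError("log-normalized values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class ReconstructedMatrix:
    """Rank-``rank_used`` reconstruction of a normalized matrix.

    Negative reconstructed entries are clamped to zero by default upstream
    (``clamp_count`` records how many), because downstream scoring assumes
    non-negative expression.
    """

    values: np.ndarray
    cell_ids: list[str]
    feature_ids: list[str]
    rank_used: int
    clamp_count: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.rank_used < 1 or self.rank_used > min(self.values.shape):
            raise ValidationError(
                f"rank_used {self.rank_used} out of bounds for shape {self.values.shape}"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def columns(self, feature_ids: list[str]) -> np.ndarray:
        """Extract the submatrix for the given feature ids, preserving order."""
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in pos]
        if missing:
            raise ValidationError(f"features absent from matrix: {missing}")
        return self.values[:, [pos[f] for f in feature_ids]]


@dataclass
class RankSelection:
    """Outcome of the elbow-based rank selection on non-centered PCs."""

    candidate_sds: np.ndarray
    selected_rank: int
    max_rank_considered: int

    def __post_init__(self) -> None:
        self.candidate_sds = np.asarray(self.candidate_sds, dtype=np.float64)
        if not (1 <= self.selected_rank <= self.max_rank_considered):
            raise ValidationError("selected_rank outside [1, max_rank_considered]")


@dataclass
class GeneSetWeights:
    """Weighted receptor gene sets: the sparse membership matrix A.

    ``sets`` maps each receptor id to an ordered list of ``(gene_id, weight)``
    pairs, sorted by decreasing weight (rank 1 = most correlated). Weights are
    the positive Spearman correlations between the reconstructed expression of
    the gene and the CLR-normalized ADT level of the receptor. Receptors for
    which no gene correlated positively carry an empty list and are skipped
    by scoring.
    """

    sets: dict[str, list[tuple[str, float]]]
    set_size_requested: int = 10
    gene_universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rec, pairs in self.sets.items():
            genes = [g for g, _ in pairs]
            if len(set(genes)) != len(genes):
                raise ValidationError(f"duplicate genes in set for {rec}")
            weights = [w for _, w in pairs]
            if any(w <= 0 for w in weights):
                raise ValidationError(f"non-positive weight in set for {rec}")
            if any(weights[i] < weights[i + 1] for i in range(len(weights) - 1)):
                raise ValidationError(f"weights not non-increasing for {rec}")

    @property
    def receptors(self) -> list[str]:
        return list(self.sets.keys())

    def scoreable(self, available_genes: set[str] | None = None) -> list[str]:
        """Receptors with a nonempty set fully contained in ``available_genes``."""
        out = []
        for rec, pairs in self.sets.items():
            if not pairs:
                continue
            if available_genes is not None and any(g not in available_genes for g, _ in pairs):
                continue
            out.append(rec)
        return out
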