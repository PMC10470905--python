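"""End-to-end receptor abundance estimation.

Training: log-normalize + reduced-rank-reconstruct the RNA counts, CLR the
paired ADT counts, and keep the top positively rank-correlated genes per
receptor as a weighted set. Estimation: normalize + reconstruct the target
RNA (rank selected independently — training and target each carry their own
reconstruction step), score each receptor's weighted set, cluster the squared
distances and zero the lowest cluster's scores. Two baselines are provided:
the naive log-normalized cognate transcript, and an unsupervised
reconstruct-then-threshold estimator assembled from the same components
(a SPECK-style approximation built from this package's own reconstruction
and clustering, not the published SPECK implementation).
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np

from .genesets import build_gene_sets
from .preprocess import clr_normalize, log_normalize, rrr_reconstruct, select_rank
from .scoring import score_receptor
from .thresholding import ckmeans_1d, threshold_scores
from .types import CountMatrix, GeneSetWeights, ValidationError

__all__ = ["RunConfig", "AbundanceEstimates", "streak_train", "streak_estimate",
           "rna_baseline", "speck_baseline", "derive_seed"]

logger = logging.getLogger(__name__)


def derive_seed(root_seed: int, stage: str) -> int:
    """Stage-specific seed below 2^31, stable across runs and platforms."""
    return int(np.random.SeedSequence(
        [int(root_seed) % (2**31), zlib.crc32(stage.encode())]
    ).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Validated parameter block shared by training and estimation."""

    set_size: int = 10
    rank: int | None = None          # None = automatic elbow selection
    max_rank: int = 100
    rank_threshold: float = 5e-3
    rank_smooth: int = 3
    seed: int = 0
    scale_factor: float = 1e4
    clr_margin: str = "per_cell"
    k_max: int = 4
    null_mode: str = "permutation"

    def __post_init__(self) -> None:
        if self.set_size < 1:
            raise ValidationError("set_size must be >= 1")
        if self.rank is not None and self.rank < 1:
            raise ValidationError("rank must be positive")
        if self.rank_threshold <= 0 or self.rank_smooth < 1:
            raise ValidationError("rank_threshold must be > 0 and rank_smooth >= 1")
        if self.k_max < 1:
            raise ValidationError("k_max must be >= 1")
        if self.null_mode not in ("permutation", "direct"):
            raise ValidationError("null_mode must be permutation or direct")
        if self.clr_margin not in ("per_cell", "per_feature"):
            raise ValidationError("clr_margin must be per_cell or per_feature")


@dataclass
class AbundanceEstimates:
    """Cells-by-receptors estimates in [0, 1] plus provenance."""

    values: np.ndarray
    cell_ids: list[str]
    receptor_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.receptor_ids)


def _reconstruct(counts: CountMatrix, config: RunConfig, stage: str):
    norm = log_normalize(counts, config.scale_factor)
    svd_seed = derive_seed(config.seed, stage + ":svd")
    if config.rank is not None:
        rank = min(config.rank, min(norm.values.shape))
    else:
        max_rank = min(config.max_rank, min(norm.values.shape))
        sel = select_rank(norm, max_rank=max_rank, seed=svd_seed,
                          threshold=config.rank_threshold, smooth=config.rank_smooth)
        rank = sel.selected_rank
        logger.info("%s: selected rank %d of %d candidates", stage, rank, max_rank)
    return rrr_reconstruct(norm, rank, seed=svd_seed), rank


def streak_train(rna_train: CountMatrix, adt_train: CountMatrix,
                 config: RunConfig | None = None) -> GeneSetWeights:
    """Learn weighted receptor gene sets from paired RNA/ADT training data."""
    config = config or RunConfig()
    if rna_train.cell_ids != adt_train.cell_ids:
        raise ValidationError("training RNA and ADT matrices must share cell ids in order")
    recon, _ = _reconstruct(rna_train, config, "train")
    adt_norm = clr_normalize(adt_train, margin=config.clr_margin)
    return build_gene_sets(recon, adt_norm, set_size=config.set_size)


def _gene_sets_hash(gene_sets: GeneSetWeights) -> str:
    payload = json.dumps(
        {r: [[g, round(w, 12)] for g, w in p] for r, p in gene_sets.sets.items()},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def streak_estimate(rna_target: CountMatrix, gene_sets: GeneSetWeights,
                    config: RunConfig | None = None) -> AbundanceEstimates:
    """Thresholded gene set scores for every scoreable receptor on target RNA.

    Receptors whose set is empty or whose genes are missing from the target
    features are skipped with a warning; at least one receptor must remain.
    """
    config = config or RunConfig()
    available = set(rna_target.feature_ids)
    receptors = gene_sets.scoreable(available)
    skipped = [r for r in gene_sets.receptors if r not in receptors]
    for r in skipped:
        logger.warning("skipping receptor %s: empty set or genes absent from target", r)
    if not receptors:
        raise ValidationError("no scoreable receptor (all sets empty or genes missing)")
    recon, rank = _reconstruct(rna_target, config, "estimate")
    out = np.empty((rna_target.n_cells, len(receptors)))
    for j, rec in enumerate(receptors):
        dist, scores, _ = score_receptor(
            recon, gene_sets.sets[rec], null_mode=config.null_mode,
            seed=derive_seed(config.seed, f"permute:{rec}"),
        )
        clustering = ckmeans_1d(dist, k_min=1, k_max=config.k_max)
        out[:, j] = threshold_scores(scores, dist, clustering)
    provenance = {
        "gene_sets_hash": _gene_sets_hash(gene_sets),
        "rank_used": rank,
        "config": asdict(config),
        "skipped_receptors": skipped,
    }
    return AbundanceEstimates(out, list(rna_target.cell_ids), receptors, provenance)


def rna_baseline(rna_target: CountMatrix, receptor_to_gene: dict[str, str],
                 scale_factor: float = 1e4) -> AbundanceEstimates:
    """Naive baseline: log-normalized cognate transcript as the estimate.

    Values are non-negative but not bounded by 1. Unmapped receptors are
    skipped with a warning.
    """
    norm = log_normalize(rna_target, scale_factor)
    pos = {g: i for i, g in enumerate(norm.feature_ids)}
    receptors, cols = [], []
    for rec, gene in receptor_to_gene.items():
        if gene not in pos:
            logger.warning("rna_baseline: gene %s for receptor %s not in features", gene, rec)
            continue
        receptors.append(rec)
        cols.append(norm.values[:, pos[gene]])
    if not receptors:
        raise ValidationError("no receptor could be mapped to a target gene")
    return AbundanceEstimates(
        np.column_stack(cols), list(rna_target.cell_ids), receptors,
        {"method": "rna_baseline"},
    )


def speck_baseline(rna_target: CountMatrix, config: RunConfig | None = None,
                   genes: list[str] | None = None) -> AbundanceEstimates:
    """Unsupervised reconstruct-then-threshold estimator (SPECK-style).

    Log-normalize, reduced-rank-reconstruct, then per gene cluster the
    reconstructed column (k up to ``config.k_max``) and zero the lowest
    cluster's values. ``genes`` restricts the (expensive) per-gene clustering
    to the columns of interest; default is all genes.
    """
    config = config or RunConfig()
    recon, rank = _reconstruct(rna_target, config, "speck")
    genes = list(genes) if genes is not None else list(rna_target.feature_ids)
    values = recon.columns(genes).copy()
    for j in range(values.shape[1]):
        col = values[:, j]
        clustering = ckmeans_1d(col, k_min=1, k_max=config.k_max)
        values[:, j] = threshold_scores(col, col, clustering)
    return AbundanceEstimates(
        values, list(rna_target.cell_ids), genes,
        {"method": "speck_baseline", "rank_used": rank},
    )
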