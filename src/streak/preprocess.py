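"""Normalization and reduced-rank reconstruction (RRR).

RNA counts are log-normalized Seurat-style: each cell's counts are scaled to
``scale_factor`` total, then ``ln(1 + .)``. ADT counts get the centered
log-ratio (CLR) transform across antibodies within each cell. The normalized
RNA matrix is then denoised by truncating its (non-centered) SVD at an
automatically selected rank and clamping negative reconstructed entries to
zero.

Rank selection follows the elbow of the non-centered principal-component
standard deviations: the smallest rank at which the smoothed consecutive SD
drop first falls below a fraction of the total drop.
"""

from __future__ import annotations

import numpy as np
from sklearn.utils.extmath import randomized_svd

from .types import CountMatrix, NormalizedMatrix, RankSelection, ReconstructedMatrix, ValidationError

__all__ = ["log_normalize", "clr_normalize", "select_rank", "rrr_reconstruct"]

#: randomized SVD settings: enough power iterations for the long-tailed
#: spectra of scRNA-seq matrices, seeded for determinism
_N_ITER = 10
_OVERSAMPLE = 10


def log_normalize(counts: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """Per-cell library-size normalization followed by ``ln(1 + x)``.

    ``value(c, g) = ln(1 + count(c, g) * scale_factor / total(c))`` where
    ``total(c)`` is cell ``c``'s summed counts. Cells with zero total counts
    are rejected.
    """
    if scale_factor <= 0:
        raise ValidationError("scale_factor must be positive")
    totals = counts.values.sum(axis=1)
    zero = totals == 0
    if np.any(zero):
        bad = [counts.cell_ids[i] for i in np.flatnonzero(zero)[:10]]
        raise ValidationError(f"cells with zero total counts: {bad}")
    vals = np.log1p(counts.values * (scale_factor / totals[:, None]))
    return NormalizedMatrix(vals, list(counts.cell_ids), list(counts.feature_ids), "lognorm")


def clr_normalize(counts: CountMatrix, margin: str = "per_cell") -> NormalizedMatrix:
    """Centered log-ratio transform with a +1 pseudocount.

    Along the chosen margin vector ``x``:
    ``out_i = log1p(x_i) - mean_j log1p(x_j)``, so the output mean along that
    margin is zero. ``per_cell`` (the default) centers across antibodies
    within each cell — the compositional reading of ADT counts; ``per_feature``
    centers each antibody across cells.
    """
    if margin not in ("per_cell", "per_feature"):
        raise ValidationError(f"margin must be per_cell or per_feature, got {margin!r}")
    logs = np.log1p(counts.values)
    axis = 1 if margin == "per_cell" else 0
    vals = logs - logs.mean(axis=axis, keepdims=True)
    return NormalizedMatrix(vals, list(counts.cell_ids), list(counts.feature_ids), "clr")


def _component_sds(values: np.ndarray, max_rank: int, seed: int) -> np.ndarray:
    m = values.shape[0]
    _, sigma, _ = randomized_svd(
        values, n_components=max_rank, n_iter=_N_ITER,
        n_oversamples=_OVERSAMPLE, random_state=int(seed) % (2**31),
    )
    return np.sort(sigma)[::-1] / np.sqrt(m - 1)


def select_rank(normalized: NormalizedMatrix, max_rank: int = 100, seed: int = 0,
                threshold: float = 5e-3, smooth: int = 3) -> RankSelection:
    """Pick the reconstruction rank at the elbow of the component-SD curve.

    The top ``max_rank`` singular values of the non-centered matrix give
    component standard deviations ``s_i = sigma_i / sqrt(m - 1)``. The rate
    of change of the curve is measured by the relative consecutive drop
    ``r_i = (s_i - s_{i+1}) / s_i``; after a ``smooth``-point moving average
    of the drops, the selected rank is the smallest ``k`` at which the curve
    has flattened, i.e. the smoothed relative drop first falls below
    ``threshold``. Relative (not absolute) drops are used because the first,
    mean-driven component of a non-centered expression matrix dwarfs the rest
    of the spectrum and would otherwise mask every later elbow. If no drop
    qualifies, ``max_rank`` is kept.
    """
    m, n = normalized.values.shape
    if m < 2:
        raise ValidationError("rank selection needs at least 2 cells")
    if max_rank > min(m, n):
        raise ValidationError(f"max_rank {max_rank} exceeds min dims {min(m, n)}")
    sds = _component_sds(normalized.values, max_rank, seed)
    if max_rank < 2 or sds[0] <= 0:
        return RankSelection(sds, 1, max_rank)
    prev = sds[:-1].copy()
    tiny = prev <= 1e-12 * sds[0]
    prev[tiny] = 1.0
    drops = -np.diff(sds) / prev
    drops[tiny] = 0.0  # spectrum already exhausted
    if smooth > 1 and drops.size >= smooth:
        drops = np.convolve(drops, np.ones(smooth) / smooth, mode="valid")
    below = np.flatnonzero(drops < threshold)
    selected = int(below[0]) + 1 if below.size else max_rank
    return RankSelection(sds, selected, max_rank)


def rrr_reconstruct(normalized: NormalizedMatrix, rank: int, seed: int = 0,
                    clamp: bool = True) -> ReconstructedMatrix:
    """Rank-``rank`` truncated-SVD reconstruction of the non-centered matrix.

    With ``clamp`` (the default) negative reconstructed entries are set to
    zero — downstream scoring treats the reconstruction as non-negative
    expression — and the number of clamped entries is recorded.
    """
    m, n = normalized.values.shape
    if not (1 <= rank <= min(m, n)):
        raise ValidationError(f"rank {rank} out of bounds for shape {(m, n)}")
    U, sigma, Vt = randomized_svd(
        normalized.values, n_components=rank, n_iter=_N_ITER,
        n_oversamples=_OVERSAMPLE, random_state=int(seed) % (2**31),
    )
    recon = (U * sigma) @ Vt
    clamp_count = 0
    if clamp:
        neg = recon < 0
        clamp_count = int(neg.sum())
        recon[neg] = 0.0
    return ReconstructedMatrix(
        recon, list(normalized.cell_ids), list(normalized.feature_ids),
        rank_used=rank, clamp_count=clamp_count,
    )
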