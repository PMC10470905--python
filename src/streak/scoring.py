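"""Weighted variance-adjusted gene set scoring.

Per receptor, each cell gets a squared modified Mahalanobis distance over the
set's reconstructed expression values: a non-centered sum of squares scaled by
inverse per-gene technical variances, with each variance divided by the gene's
set weight so highly weighted genes contribute more. A null distribution of
distances is obtained by independently permuting each gene column, a gamma
distribution is fitted to the nonzero null distances by maximum likelihood,
and the cell's score is the fitted gamma CDF evaluated at its observed
distance — a value in [0, 1] that is monotone in the distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, polygamma
from scipy.stats import gamma as gamma_dist

from .types import GeneSetWeights, ReconstructedMatrix, ValidationError

__all__ = [
    "TechnicalVariances",
    "GammaParams",
    "technical_variance",
    "modified_mahalanobis",
    "permute_within_columns",
    "fit_gamma_mle",
    "score_receptor",
    "GammaFitError",
]

logger = logging.getLogger(__name__)

#: relative floor applied to zero-variance genes within a set
_VAR_FLOOR_REL = 1e-12


class GammaFitError(ValueError):
    """Too few distinct nonzero distances to calibrate a gamma null."""


@dataclass
class TechnicalVariances:
    """Per-gene technical variance estimates (here: plain sample variances)."""

    variances: np.ndarray
    gene_ids: list[str]
    method: str = "sample_variance"


@dataclass
class GammaParams:
    shape: float
    rate: float
    n_used: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.shape) and np.isfinite(self.rate)
                and self.shape > 0 and self.rate > 0):
            raise ValidationError(f"invalid gamma parameters ({self.shape}, {self.rate})")


def technical_variance(recon: ReconstructedMatrix, genes: list[str]) -> TechnicalVariances:
    """Unbiased sample variance of each listed gene column.

    Treats the observed marginal variance of the reconstructed expression as
    entirely technical.
    """
    cols = recon.columns(list(genes))
    var = cols.var(axis=0, ddof=1)
    return TechnicalVariances(var, list(genes))


def _effective_variances(tech_var: TechnicalVariances, weights: np.ndarray) -> np.ndarray:
    var = np.asarray(tech_var.variances, dtype=np.float64).copy()
    if np.all(var == 0):
        raise ValidationError("all set genes have zero variance; set cannot be scored")
    floor = _VAR_FLOOR_REL * var.max()
    var[var < floor] = floor
    return var / weights


def modified_mahalanobis(set_values: np.ndarray, tech_var: TechnicalVariances,
                         weights: np.ndarray) -> np.ndarray:
    """Squared modified Mahalanobis distance per cell (no centering).

    ``d(c) = sum_j set_values(c, j)^2 / (var_j / w_j)``. Dividing each
    variance by its weight shrinks the effective variance of highly weighted
    genes, inflating their contribution to the distance.
    """
    set_values = np.asarray(set_values, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if set_values.ndim != 2 or set_values.shape[1] != weights.size:
        raise ValidationError("set_values columns must align with weights")
    if np.any(weights <= 0):
        raise ValidationError("weights must be strictly positive")
    if len(tech_var.variances) != weights.size:
        raise ValidationError("technical variances must align with weights")
    eff = _effective_variances(tech_var, weights)
    return (set_values**2 / eff).sum(axis=1)


def permute_within_columns(matrix: np.ndarray, seed: int) -> np.ndarray:
    """Independently shuffle the rows of each column (seeded).

    Breaks between-gene correlation while preserving each gene's marginal
    distribution — the null under which only technical variance remains.
    """
    rng = np.random.default_rng(seed)
    matrix = np.asarray(matrix)
    out = np.empty_like(matrix)
    for j in range(matrix.shape[1]):
        out[:, j] = matrix[rng.permutation(matrix.shape[0]), j]
    return out


def fit_gamma_mle(distances: np.ndarray, tol: float = 1e-9,
                  max_iter: int = 200) -> GammaParams:
    """Maximum-likelihood gamma fit to the nonzero distances.

    Newton iteration on the profile equation
    ``log(a) - digamma(a) = log(mean(x)) - mean(log(x))``
    from the standard closed-form start; ``rate = a / mean(x)``. Requires at
    least two distinct nonzero values, otherwise raises :class:`GammaFitError`
    and the caller falls back to min-max scaled distances.
    """
    x = np.asarray(distances, dtype=np.float64)
    x = x[x > 0]
    if x.size < 2 or np.unique(x).size < 2:
        raise GammaFitError("need >= 2 distinct nonzero distances")
    m = x.mean()
    s = np.log(m) - np.mean(np.log(x))
    if s <= 0:  # numerically degenerate (near-constant data)
        raise GammaFitError("degenerate log-moment statistic")
    a = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(max_iter):
        f = np.log(a) - digamma(a) - s
        fprime = 1.0 / a - polygamma(1, a)
        step = f / fprime
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2.0
        if abs(a_new - a) < tol:
            a = a_new
            break
        a = a_new
    return GammaParams(shape=float(a), rate=float(a / m), n_used=int(x.size))


def score_receptor(recon_target: ReconstructedMatrix, gene_set: list[tuple[str, float]],
                   null_mode: str = "permutation", seed: int = 0,
                   ) -> tuple[np.ndarray, np.ndarray, GammaParams | None]:
    """Distances, gamma-CDF scores and fitted null parameters for one receptor.

    Parameters
    ----------
    gene_set
        Ordered ``(gene_id, weight)`` pairs; every gene must be present in
        ``recon_target``.
    null_mode
        ``"permutation"`` fits the gamma to distances of a column-permuted
        copy; ``"direct"`` fits it to the observed distances, trading the
        explicit null for speed.

    Returns ``(distances, scores, params)``; ``params`` is None when the
    gamma calibration was degenerate and min-max scaling was used instead.
    """
    if null_mode not in ("permutation", "direct"):
        raise ValidationError(f"null_mode must be permutation or direct, got {null_mode!r}")
    if not gene_set:
        raise ValidationError("empty gene set")
    genes = [g for g, _ in gene_set]
    weights = np.array([w for _, w in gene_set], dtype=np.float64)
    set_values = recon_target.columns(genes)  # raises listing missing genes
    tech = technical_variance(recon_target, genes)
    distances = modified_mahalanobis(set_values, tech, weights)
    if null_mode == "permutation":
        null_values = permute_within_columns(set_values, seed)
        null_distances = modified_mahalanobis(null_values, tech, weights)
    else:
        null_distances = distances
    try:
        params = fit_gamma_mle(null_distances)
    except GammaFitError:
        logger.warning("gamma calibration degenerate; falling back to min-max scaled distances")
        span = distances.max() - distances.min()
        scores = (distances - distances.min()) / span if span > 0 else np.zeros_like(distances)
        return distances, scores, None
    scores = gamma_dist.cdf(distances, a=params.shape, scale=1.0 / params.rate)
    return distances, scores, params
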