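"""Optimal univariate k-means clustering and least-cluster score zeroing.

The squared distances of a receptor are clustered into between ``k_min`` and
``k_max`` groups by exact dynamic programming over the sorted values — the
partition into contiguous intervals minimizing total within-cluster sum of
squares, for each candidate k. The number of clusters is then chosen by the
Bayesian information criterion under a Gaussian mixture of the clusters.
Cells falling in the lowest-mean cluster are called "receptor absent" and
their scores are set to zero; a single cluster means no thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ValidationError

__all__ = ["Clustering1D", "ckmeans_1d", "threshold_scores"]

_BIC_VAR_FLOOR = 1e-12


@dataclass
class Clustering1D:
    """Exact 1-D clustering result.

    ``assignments`` are 1-based cluster indices in original input order;
    clusters are contiguous intervals of the sorted values, so ``centers``
    is ascending.
    """

    assignments: np.ndarray
    centers: np.ndarray
    k_selected: int
    within_ss: float


def _dp_partition(xs: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Optimal partition of sorted ``xs`` into ``k`` contiguous clusters.

    Returns the (k+1)-vector of breakpoints (cluster c = xs[b[c]:b[c+1]])
    and the minimal total within-cluster sum of squares.
    """
    n = xs.size
    cum = np.concatenate(([0.0], np.cumsum(xs)))
    cum2 = np.concatenate(([0.0], np.cumsum(xs * xs)))

    def seg_cost(j: np.ndarray | int, i: int) -> np.ndarray:
        # SSE of xs[j..i] inclusive
        length = i - np.asarray(j) + 1
        s = cum[i + 1] - cum[j]
        return (cum2[i + 1] - cum2[j]) - s * s / length

    # D[i] = optimal cost for xs[0..i] at the current level (1 cluster first)
    lengths = np.arange(1, n + 1, dtype=np.float64)
    s = cum[1:] - cum[0]
    D = (cum2[1:] - cum2[0]) - s * s / lengths
    back: list[np.ndarray] = []
    for level in range(2, k + 1):
        Dn = np.full(n, np.inf)
        Bn = np.zeros(n, dtype=np.int64)
        for i in range(level - 1, n):
            j = np.arange(level - 1, i + 1)
            cand = D[j - 1] + seg_cost(j, i)
            best = int(np.argmin(cand))
            Dn[i] = cand[best]
            Bn[i] = j[best]
        D = Dn
        back.append(Bn)
    breaks = np.empty(k + 1, dtype=np.int64)
    breaks[0], breaks[k] = 0, n
    i = n - 1
    for level in range(k, 1, -1):
        j = int(back[level - 2][i])
        breaks[level - 1] = j
        i = j - 1
    return breaks, float(D[n - 1])


def _bic(xs: np.ndarray, breaks: np.ndarray) -> float:
    """BIC of a Gaussian mixture with one component per contiguous cluster."""
    n = xs.size
    k = breaks.size - 1
    loglik = 0.0
    for c in range(k):
        seg = xs[breaks[c]:breaks[c + 1]]
        nc = seg.size
        var = max(seg.var(), _BIC_VAR_FLOOR)
        loglik += nc * np.log(nc / n)
        loglik += -0.5 * nc * np.log(2 * np.pi * var) - 0.5 * ((seg - seg.mean()) ** 2).sum() / var
    n_params = 3 * k - 1  # k means, k variances, k-1 mixing proportions
    return -2.0 * loglik + n_params * np.log(n)


def ckmeans_1d(values: np.ndarray, k_min: int = 1, k_max: int = 4) -> Clustering1D:
    """Exactly optimal 1-D k-means with BIC selection of k.

    For each k in ``[k_min, min(k_max, #distinct values)]`` the DP computes
    the minimum within-SS contiguous partition of the sorted values; the k
    with the smallest mixture BIC wins, ties resolved toward smaller k.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValidationError("cannot cluster an empty vector")
    if not (1 <= k_min <= k_max):
        raise ValidationError("need 1 <= k_min <= k_max")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n_distinct = np.unique(xs).size
    k_hi = min(k_max, n_distinct, x.size)
    k_lo = min(k_min, k_hi)
    best: tuple[float, int, np.ndarray, float] | None = None
    for k in range(k_lo, k_hi + 1):
        breaks, wss = _dp_partition(xs, k)
        bic = _bic(xs, breaks)
        if best is None or bic < best[0]:
            best = (bic, k, breaks, wss)
    _, k_sel, breaks, wss = best
    assign_sorted = np.empty(x.size, dtype=np.int64)
    centers = np.empty(k_sel)
    for c in range(k_sel):
        assign_sorted[breaks[c]:breaks[c + 1]] = c + 1
        centers[c] = xs[breaks[c]:breaks[c + 1]].mean()
    assignments = np.empty(x.size, dtype=np.int64)
    assignments[order] = assign_sorted
    return Clustering1D(assignments, centers, int(k_sel), wss)


def threshold_scores(scores: np.ndarray, distances: np.ndarray,
                     clustering: Clustering1D) -> np.ndarray:
    """Zero the scores of cells in the lowest-center distance cluster.

    With a single cluster the scores pass through unchanged. Only zeroing
    happens — no score is ever increased or otherwise altered, so the
    operation is idempotent.
    """
    scores = np.asarray(scores, dtype=np.float64)
    distances = np.asarray(distances, dtype=np.float64)
    if not (scores.shape == distances.shape == clustering.assignments.shape):
        raise ValidationError("scores, distances and assignments must align")
    if clustering.k_selected <= 1:
        return scores.copy()
    least = int(np.argmin(clustering.centers)) + 1
    out = scores.copy()
    out[clustering.assignments == least] = 0.0
    return out
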