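"""Maximal information coefficient (MIC) via constrained grid search.

MIC is the maximum, over all x-by-y grids with x*y <= B(n) = n^0.6, of the
normalized mutual information I(X;Y|grid) / log min(x, y).  The search uses
the standard heuristic: for each number of y bins the y axis is equipartitioned
(equal-frequency), candidate x boundaries are restricted to clumps (runs of
equal x, coarsened into superclumps when too numerous), and a dynamic program
finds the optimal x partition for every x-bin count at once.  The procedure is
run in both axis orientations and the best normalized score is kept.
"""

from __future__ import annotations

import numpy as np

__all__ = ["mic"]


def _equifreq_bins(v: np.ndarray, q: int) -> np.ndarray:
    """Rank-based equal-frequency bin assignment (ties share a bin)."""
    n = v.size
    order = np.argsort(v, kind="stable")
    sorted_v = v[order]
    # lower-CDF group assignment (same rule as equal-probability quantization)
    first = np.concatenate(([0], np.nonzero(np.diff(sorted_v))[0] + 1))
    gid = np.cumsum(np.concatenate(([0], (np.diff(sorted_v) != 0).astype(int))))
    below = first[gid]
    bins = np.empty(n, dtype=np.int64)
    bins[order] = (q * below) // n
    return np.minimum(bins, q - 1)


def _clump_boundaries(x_sorted: np.ndarray, max_clumps: int) -> np.ndarray:
    """Prefix sizes of candidate x-bin boundaries (0 and n included).

    Boundaries never split a run of equal x; if there are more runs than
    ``max_clumps`` they are coarsened into equal-size superclumps.
    """
    n = x_sorted.size
    change = np.nonzero(np.diff(x_sorted))[0] + 1
    bounds = np.concatenate(([0], change, [n]))
    m = bounds.size - 1
    if m <= max_clumps:
        return bounds
    # superclumps: snap the equipartition targets onto existing clump edges
    targets = np.linspace(0, n, max_clumps + 1)
    picked = bounds[np.searchsorted(bounds, targets, side="left").clip(0, bounds.size - 1)]
    return np.unique(np.concatenate(([0], picked, [n])))


def _optimize_axis(xv: np.ndarray, yv: np.ndarray, q: int, maxx: int, c_hat: int):
    """Best mutual information for each x-bin count 2..maxx, y equipartitioned."""
    n = xv.size
    order = np.argsort(xv, kind="stable")
    xs = xv[order]
    yb = _equifreq_bins(yv, q)[order]

    bounds = _clump_boundaries(xs, c_hat * maxx)
    m = bounds.size - 1
    if m < 2:
        return np.zeros(0)

    # prefix y-bin counts at each boundary
    onehot = np.zeros((n + 1, q))
    np.add.at(onehot, (np.arange(1, n + 1), yb), 1.0)
    pref = np.cumsum(onehot, axis=0)[bounds]  # (m+1, q)
    K = bounds.astype(float)

    ny = pref[-1]
    pq = ny[ny > 0] / n
    hq = -(pq * np.log(pq)).sum()

    # T[j, i] = -(c/n)log(c/n) + sum_y (cy/n)log(cy/n) for the bin (j, i]
    C = K[None, :] - K[:, None]
    CY = pref[None, :, :] - pref[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        pc = C / n
        t1 = -np.where(C > 0, pc * np.log(pc), 0.0)
        pcy = CY / n
        t2 = np.where(CY > 0, pcy * np.log(pcy), 0.0).sum(axis=2)
    T = t1 + t2
    T[np.tril_indices(m + 1)] = -np.inf  # only j < i feasible

    scores = np.full(maxx + 1, -np.inf)
    F = T[0].copy()  # l = 1: single bin over the prefix, must start at 0
    for l in range(2, maxx + 1):
        F = np.max(F[:, None] + T, axis=0)
        scores[l] = F[-1]
    out = hq + scores[2:]
    return out  # index k -> l = k + 2


def mic(x, y, alpha: float = 0.6, c_hat: int = 5) -> float:
    """MIC in [0, 1]; 0 for constant input, ~1 for noiseless functional relations."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    n = x.size
    if n < 10:
        raise ValueError("MIC requires at least 10 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    b = max(int(n**alpha), 4)
    best = 0.0
    for xv, yv in ((x, y), (y, x)):
        for q in range(2, b // 2 + 1):
            maxx = b // q
            if maxx < 2:
                break
            vals = _optimize_axis(xv, yv, q, maxx, c_hat)
            for k, val in enumerate(vals):
                l = k + 2
                if np.isfinite(val) and val > 0:
                    best = max(best, val / np.log(min(l, q)))
    return float(min(best, 1.0))
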