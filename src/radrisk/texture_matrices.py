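"""3D texture matrices (GLCM, GLRLM, GLSZM, NGTDM) from a quantized ROI.

All four matrices are built with merged 13-direction / 26-connectivity 3D
analysis: a single matrix per scan, accumulating the contributions of every
direction, rather than one matrix per direction.  The 6 face, 12 edge and 8
corner neighbours sit at Euclidean distances 1, sqrt(2) and sqrt(3) on the
isotropic grid and are treated distance-aware:

* GLCM pair contributions and NGTDM neighbourhood averages are weighted by
  inverse Euclidean distance (1, 1/sqrt2, 1/sqrt3), equalizing the per-unit-
  length sampling density of the three neighbour classes;
* GLRLM run lengths accumulate the geometric step length, so a k-voxel run
  along an edge/corner diagonal covers 1 + (k-1)*sqrt(2 or 3) and is binned
  into the nearest integer length column (a single voxel is always a length-1
  run).

Both behaviours can be switched off (``weighted=False``) to recover the
plain voxel-count convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_core import QuantizedROI

__all__ = [
    "DIRECTIONS",
    "GLCM",
    "GLRLM",
    "GLSZM",
    "NGTDM",
    "build_glcm",
    "build_glrlm",
    "build_glszm",
    "build_ngtdm",
]


def _canonical_directions() -> list[tuple[int, int, int]]:
    """The 13 offsets covering half of the 26-neighbourhood (first nonzero > 0)."""
    dirs = []
    for a in (-1, 0, 1):
        for b in (-1, 0, 1):
            for c in (-1, 0, 1):
                v = (a, b, c)
                if v == (0, 0, 0):
                    continue
                first = next(x for x in v if x != 0)
                if first > 0:
                    dirs.append(v)
    assert len(dirs) == 13
    return dirs


DIRECTIONS: tuple[tuple[int, int, int], ...] = tuple(_canonical_directions())


def _step_length(d: tuple[int, int, int]) -> float:
    return float(np.sqrt(sum(x * x for x in d)))


@dataclass(frozen=True)
class GLCM:
    """Normalized symmetric gray-level co-occurrence matrix.

    ``degenerate`` flags ROIs with no voxel pairs (single voxel): the matrix
    is all zero and feature code falls back to single-level rules using
    ``solo_level``.
    """

    m: np.ndarray
    n_gray: int
    degenerate: bool = False
    solo_level: int | None = None


@dataclass(frozen=True)
class GLRLM:
    """Gray-level run-length matrix of run counts (levels x run length)."""

    m: np.ndarray
    n_gray: int


@dataclass(frozen=True)
class GLSZM:
    """Gray-level size-zone matrix of 26-connected zone counts (levels x size)."""

    m: np.ndarray
    n_gray: int


@dataclass(frozen=True)
class NGTDM:
    """Neighbourhood gray-tone difference vector.

    ``s[g]`` accumulates |level - neighbourhood average| over in-ROI voxels of
    level g+1; ``p[g]`` is the occurrence probability of level g+1 among the
    counted voxels (those with at least one in-ROI neighbour).
    """

    s: np.ndarray
    p: np.ndarray
    n_gray: int
    n_counted: int


def _shifted_views(arr: np.ndarray, d: tuple[int, int, int]):
    """Aligned views (a, b) such that b is a shifted by offset d."""
    sl_a, sl_b = [], []
    for ax, off in enumerate(d):
        n = arr.shape[ax]
        if off == 0:
            sl_a.append(slice(0, n))
            sl_b.append(slice(0, n))
        elif off > 0:
            sl_a.append(slice(0, n - off))
            sl_b.append(slice(off, n))
        else:
            sl_a.append(slice(-off, n))
            sl_b.append(slice(0, n + off))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


def build_glcm(q: QuantizedROI, weighted: bool = True) -> GLCM:
    """Single merged co-occurrence matrix over the 13 directions.

    Each unordered in-ROI voxel pair at Chebyshev distance 1 contributes once,
    weighted by inverse Euclidean distance, after which the matrix is
    symmetrized and normalized to sum 1.
    """
    g = q.n_gray
    L = q.levels
    acc = np.zeros((g, g), dtype=float)
    for d in DIRECTIONS:
        a, b = _shifted_views(L, d)
        if a.size == 0:
            continue
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        w = 1.0 / _step_length(d) if weighted else 1.0
        pairs = (a[valid] - 1) * g + (b[valid] - 1)
        acc += w * np.bincount(pairs, minlength=g * g).reshape(g, g)
    acc = acc + acc.T
    total = acc.sum()
    if total == 0:
        solo = int(L[L > 0][0])
        return GLCM(acc, g, degenerate=True, solo_level=solo)
    return GLCM(acc / total, g)


def build_glrlm(q: QuantizedROI, weighted: bool = True) -> GLRLM:
    """Run-length matrix merged over the 13 directions.

    Along each direction every in-ROI voxel belongs to exactly one maximal run
    of equal gray level; runs are broken by out-of-ROI voxels and grid edges.
    """
    g = q.n_gray
    L = q.levels
    shape = L.shape
    coords = np.indices(shape).reshape(3, -1)
    flat = L.ravel()
    run_levels: list[np.ndarray] = []
    run_cols: list[np.ndarray] = []
    max_col = 1
    for d in DIRECTIONS:
        dlen = _step_length(d) if weighted else 1.0
        ax = next(i for i in range(3) if d[i] != 0)  # axis advancing +1 per step
        t = coords[ax]
        line_id = coords - t[None, :] * np.asarray(d)[:, None]
        order = np.lexsort((t, line_id[2], line_id[1], line_id[0]))
        lv = flat[order]
        lid = line_id[:, order]
        ts = t[order]
        new_run = np.ones(lv.size, dtype=bool)
        if lv.size > 1:
            same_line = (np.diff(lid, axis=1) == 0).all(axis=0)
            contiguous = np.diff(ts) == 1
            same_level = np.diff(lv) == 0
            new_run[1:] = ~(same_line & contiguous & same_level)
        rid = np.cumsum(new_run) - 1
        counts = np.bincount(rid)
        start_level = lv[new_run]
        keep = start_level > 0
        k = counts[keep].astype(float)
        col = np.floor(1.0 + (k - 1.0) * dlen + 0.5).astype(np.int64)
        run_levels.append(start_level[keep])
        run_cols.append(col)
        if col.size:
            max_col = max(max_col, int(col.max()))
    m = np.zeros((g, max_col), dtype=float)
    for lvs, cols in zip(run_levels, run_cols):
        np.add.at(m, (lvs - 1, cols - 1), 1.0)
    return GLRLM(m, g)


def build_glszm(q: QuantizedROI) -> GLSZM:
    """Size-zone matrix: maximal 26-connected components of equal gray level."""
    g = q.n_gray
    L = q.levels
    structure = np.ones((3, 3, 3), dtype=int)
    zones: list[tuple[int, np.ndarray]] = []
    max_size = 1
    present = np.unique(L[L > 0])
    for lev in present:
        lab, n = ndimage.label(L == lev, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zones.append((int(lev), sizes))
        max_size = max(max_size, int(sizes.max()))
    m = np.zeros((g, max_size), dtype=float)
    for lev, sizes in zones:
        m[lev - 1] += np.bincount(sizes, minlength=max_size + 1)[1:].astype(float)
    return GLSZM(m, g)


def build_ngtdm(q: QuantizedROI, weighted: bool = True) -> NGTDM:
    """Neighbourhood gray-tone difference vector with distance-weighted averages.

    For each in-ROI voxel the neighbourhood average is the inverse-distance
    weighted mean of its in-ROI 26-neighbours; voxels with no in-ROI
    neighbour contribute nothing (and are excluded from the probabilities).
    """
    g = q.n_gray
    L = q.levels.astype(float)
    inroi = (q.levels > 0).astype(float)
    kern = np.zeros((3, 3, 3))
    for a in (-1, 0, 1):
        for b in (-1, 0, 1):
            for c in (-1, 0, 1):
                if (a, b, c) == (0, 0, 0):
                    continue
                dist = np.sqrt(a * a + b * b + c * c)
                kern[a + 1, b + 1, c + 1] = 1.0 / dist if weighted else 1.0
    wsum = ndimage.correlate(inroi, kern, mode="constant", cval=0.0)
    vsum = ndimage.correlate(L * inroi, kern, mode="constant", cval=0.0)
    counted = (q.levels > 0) & (wsum > 1e-12)
    avg = np.zeros_like(wsum)
    avg[counted] = vsum[counted] / wsum[counted]
    s = np.zeros(g)
    counts = np.zeros(g)
    lv = q.levels[counted]
    diffs = np.abs(q.levels[counted].astype(float) - avg[counted])
    np.add.at(s, lv - 1, diffs)
    np.add.at(counts, lv - 1, 1.0)
    n_counted = int(counts.sum())
    p = counts / n_counted if n_counted else counts
    return NGTDM(s, p, g, n_counted)
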