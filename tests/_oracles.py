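"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain nested loops over voxels/pairs, kept
deliberately naive and separate from the package's vectorized code paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

SQ = {1: 1.0, 2: math.sqrt(2.0), 3: math.sqrt(3.0)}

ALL_26 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]
HALF_13 = [d for d in ALL_26 if next(x for x in d if x != 0) > 0]


def _dist(d):
    return SQ[abs(d[0]) + abs(d[1]) + abs(d[2])]


def _inside(shape, v):
    return all(0 <= v[i] < shape[i] for i in range(3))


def glcm_oracle(levels: np.ndarray, n_gray: int, weighted: bool = True) -> np.ndarray:
    """Loop over all voxel pairs in the 13 directions; unordered pairs once,
    weighted by inverse distance, symmetrized, normalized."""
    acc = np.zeros((n_gray, n_gray))
    shape = levels.shape
    for v in itertools.product(*[range(s) for s in shape]):
        la = levels[v]
        if la == 0:
            continue
        for d in HALF_13:
            u = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if not _inside(shape, u):
                continue
            lb = levels[u]
            if lb == 0:
                continue
            w = 1.0 / _dist(d) if weighted else 1.0
            acc[la - 1, lb - 1] += w
    acc = acc + acc.T
    t = acc.sum()
    return acc / t if t > 0 else acc


def glrlm_oracle(levels: np.ndarray, n_gray: int, weighted: bool = True) -> np.ndarray:
    """Scan each direction voxel-by-voxel; a run starts where the backward
    neighbour breaks; run length = round_half_up(1 + (k-1)*step)."""
    shape = levels.shape
    runs = []  # (level, column)
    for d in HALF_13:
        step = _dist(d) if weighted else 1.0
        for v in itertools.product(*[range(s) for s in shape]):
            lv = levels[v]
            if lv == 0:
                continue
            back = (v[0] - d[0], v[1] - d[1], v[2] - d[2])
            if _inside(shape, back) and levels[back] == lv:
                continue  # not a run start
            k = 1
            nxt = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            while _inside(shape, nxt) and levels[nxt] == lv:
                k += 1
                nxt = (nxt[0] + d[0], nxt[1] + d[1], nxt[2] + d[2])
            col = int(math.floor(1.0 + (k - 1) * step + 0.5))
            runs.append((lv, col))
    max_col = max((c for _, c in runs), default=1)
    m = np.zeros((n_gray, max_col))
    for lv, col in runs:
        m[lv - 1, col - 1] += 1
    return m


def glszm_oracle(levels: np.ndarray, n_gray: int) -> np.ndarray:
    """Flood-fill 26-connected zones of equal level."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for v in itertools.product(*[range(s) for s in shape]):
        if levels[v] == 0 or seen[v]:
            continue
        lv = levels[v]
        stack = [v]
        seen[v] = True
        size = 0
        while stack:
            u = stack.pop()
            size += 1
            for d in ALL_26:
                w = (u[0] + d[0], u[1] + d[1], u[2] + d[2])
                if _inside(shape, w) and not seen[w] and levels[w] == lv:
                    seen[w] = True
                    stack.append(w)
        zones.append((lv, size))
    max_size = max((s for _, s in zones), default=1)
    m = np.zeros((n_gray, max_size))
    for lv, size in zones:
        m[lv - 1, size - 1] += 1
    return m


def ngtdm_oracle(levels: np.ndarray, n_gray: int, weighted: bool = True):
    """Per-voxel weighted neighbourhood averages; returns (s, p, n_counted)."""
    shape = levels.shape
    s = np.zeros(n_gray)
    counts = np.zeros(n_gray)
    for v in itertools.product(*[range(sz) for sz in shape]):
        lv = levels[v]
        if lv == 0:
            continue
        wsum = 0.0
        vsum = 0.0
        for d in ALL_26:
            u = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _inside(shape, u) and levels[u] != 0:
                w = 1.0 / _dist(d) if weighted else 1.0
                wsum += w
                vsum += w * levels[u]
        if wsum == 0:
            continue
        s[lv - 1] += abs(lv - vsum / wsum)
        counts[lv - 1] += 1
    n = counts.sum()
    p = counts / n if n else counts
    return s, p, int(n)


# ---------------------------------------------------------------------------
# metric oracles


def auc_pair_oracle(scores, labels) -> float:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = conc = 0.0
    for a in pos:
        for b in neg:
            total += 1
            if a > b:
                conc += 1
            elif a == b:
                conc += 0.5
    return conc / total


def ci_pair_oracle(risk, time, event) -> float:
    n = len(risk)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


def bh_oracle(p, q) -> np.ndarray:
    """Exhaustive search for the largest k with p_(k) <= k q / m."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    flags = np.zeros(m, dtype=bool)
    flags[order[:k_star]] = True
    return flags


def logrank_oracle(time, event, group):
    """Two-group log-rank chi-square from the classic O-E table."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    labels = np.unique(group)
    assert len(labels) == 2
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        d = ((time == t) & (event == 1)).sum()
        n1 = (at_risk & (group == labels[0])).sum()
        d1 = ((time == t) & (event == 1) & (group == labels[0])).sum()
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2


def mic_small_oracle(x, y, b: int) -> float:
    """Exhaustive MIC over all grid placements for tiny n (<= ~12).

    Enumerates every x- and y-axis partition (cuts between sorted distinct
    values) for every (nx, ny) with nx*ny <= b.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size

    def partitions(v, k):
        cuts = sorted(set(v))[:-1]  # cut after each distinct value
        out = []
        for ch in itertools.combinations(cuts, k - 1):
            bins = np.zeros(n, dtype=int)
            for e in ch:  # values above a cut go to the upper bin
                bins += v > e
            out.append(bins)
        return out

    best = 0.0
    for nx in range(2, b + 1):
        for ny in range(2, b // nx + 1):
            for xb in partitions(x, nx):
                for yb in partitions(y, ny):
                    joint = np.zeros((nx, ny))
                    for i in range(n):
                        joint[xb[i], yb[i]] += 1
                    joint /= n
                    px = joint.sum(1)
                    py = joint.sum(0)
                    mi = 0.0
                    for a in range(nx):
                        for c in range(ny):
                            if joint[a, c] > 0:
                                mi += joint[a, c] * math.log(
                                    joint[a, c] / (px[a] * py[c])
                                )
                    best = max(best, mi / math.log(min(nx, ny)))
    return min(best, 1.0)
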