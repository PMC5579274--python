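"""Imbalance adjustment by balanced partition ensembles.

A training sample with N- majority (non-event) and N+ minority (event)
instances is split into P = round(N-/N+) partitions: the minority instances
are copied into every partition while the majority instances are sampled
without replacement across partitions, so each partition is approximately
balanced and the union of majority parts recovers the majority set exactly.
One classifier is trained per partition and the ensemble is combined
downstream (coefficient averaging for logistic models, tree appending for
forests).  On top of the partitioning, the minority class can be under- or
oversampled by a weight w in [0.5, 2.0].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["PartitionPlan", "plan_partitions", "apply_class_weight", "weight_grid"]


@dataclass(frozen=True)
class PartitionPlan:
    """Ensemble layout: minority copied everywhere, majority split evenly."""

    partitions: tuple[tuple[np.ndarray, np.ndarray], ...]  # (majority_part, minority) per partition
    minority_indices: np.ndarray
    majority_indices: np.ndarray

    @property
    def P(self) -> int:
        return len(self.partitions)

    def partition_indices(self, k: int) -> np.ndarray:
        """All instance indices (majority part + copied minority) of partition k."""
        maj, mino = self.partitions[k]
        return np.concatenate([maj, mino])

    def majority_sizes(self) -> list[int]:
        return [len(maj) for maj, _ in self.partitions]

    def to_json(self) -> str:
        return json.dumps(
            {
                "P": self.P,
                "minority": self.minority_indices.tolist(),
                "majority_parts": [maj.tolist() for maj, _ in self.partitions],
            }
        )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def plan_partitions(majority_idx, minority_idx, rng_seed=None) -> PartitionPlan:
    """Build the balanced-partition ensemble plan.

    P = round(N-/N+) (half-up); the majority set is shuffled and dealt into P
    parts of size floor(N-/P) or ceil(N-/P); every part is paired with the
    full minority set.  Deterministic under a fixed seed.
    """
    majority = np.asarray(majority_idx)
    minority = np.asarray(minority_idx)
    n_min = minority.size
    n_maj = majority.size
    if n_min == 0:
        raise ValueError("no minority (event) instances in sample")
    if n_maj < n_min:
        warnings.warn(
            "majority class smaller than minority: swapping roles", stacklevel=2
        )
        majority, minority = minority, majority
        n_maj, n_min = n_min, n_maj
    rng = np.random.default_rng(rng_seed)
    p = max(_round_half_up(n_maj / n_min), 1)
    shuffled = rng.permutation(majority)
    # deal into p parts differing in size by at most one, covering all of majority
    base = n_maj // p
    extra = n_maj % p
    sizes = [base + 1 if k < extra else base for k in range(p)]
    parts = []
    pos = 0
    for sz in sizes:
        parts.append((shuffled[pos : pos + sz], minority.copy()))
        pos += sz
    return PartitionPlan(tuple(parts), minority, majority)


def apply_class_weight(partition, w: float, rng_seed=None) -> np.ndarray:
    """Resample the minority side of one partition to round(w * N+) slots.

    w < 1 undersamples without replacement; w > 1 first duplicates every
    minority instance once, then fills the remaining slots with replacement,
    so each original instance appears at least once; w = 1 is the identity.
    Returns the full index multiset (majority part + resampled minority).
    """
    maj, mino = partition
    if not 0.5 <= w <= 2.0:
        raise ValueError("weight must lie in [0.5, 2.0]")
    n_min = mino.size
    target = _round_half_up(w * n_min)
    if target == 0:
        raise ValueError("weight removes all minority instances")
    rng = np.random.default_rng(rng_seed)
    if target == n_min:
        res = mino
    elif target < n_min:
        res = rng.choice(mino, size=target, replace=False)
    else:
        extra = rng.choice(mino, size=target - n_min, replace=True)
        res = np.concatenate([mino, extra])
    return np.concatenate([maj, res])


def weight_grid(lo: float = 0.5, hi: float = 2.0, step: float = 0.1) -> np.ndarray:
    """The minority under/oversampling weight grid (16 values by default)."""
    n = int(round((hi - lo) / step)) + 1
    return np.round(np.linspace(lo, hi, n), 10)
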