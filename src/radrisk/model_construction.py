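"""Radiomic model construction: Gain-based feature-set reduction, imbalance-
adjusted 0.632+ bootstrap forward selection over model orders 1-10, and final
bootstrap-averaged logistic models.

The pipeline mirrors common radiomics practice: (1) reduce the feature battery
to 25 candidates balancing univariate predictive power (|Spearman rho| against
the binary outcome) and non-redundancy (1 - mean MIC to the already-selected
features); (2) grow models of order 1..10 by greedy forward selection
maximizing the 0.632+ bootstrap AUC, each bootstrap classifier being a
balanced partition ensemble with averaged coefficients; (3) pick the smallest
order within one standard error of the best estimate; (4) average final
coefficients over a fresh set of bootstrap samples.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .imbalance import plan_partitions
from .mic import mic
from .stats_core import auc_mann_whitney, spearman

__all__ = [
    "ReducedFeatureSet",
    "LogisticModel",
    "reduce_feature_set",
    "combine_632plus",
    "auc_632plus",
    "forward_select",
    "choose_order",
    "finalize_logistic",
    "fit_logistic",
]


# ---------------------------------------------------------------------------
# plain logistic fit (IRLS); the modelling loops run ~1e4-1e5 tiny fits, so a
# minimal Newton solver with a ridge fallback is used instead of a heavier API


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 1e-8,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> tuple[float, np.ndarray]:
    """Maximum-likelihood logistic fit; returns (intercept, coefficients).

    Features are standardized internally for conditioning and coefficients
    returned on the raw scale.  Zero-variance columns get coefficient 0.
    Quasi-separation (diverging standardized coefficients) triggers a refit
    with a small ridge penalty.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    const = sd == 0
    sd_safe = np.where(const, 1.0, sd)
    Z = np.column_stack([np.ones(n), (X - mu) / sd_safe])
    Z[:, 1:][:, const] = 0.0

    def _irls(lam: float):
        beta = np.zeros(p + 1)
        pen = np.full(p + 1, lam)
        pen[0] = 0.0
        for _ in range(max_iter):
            eta = np.clip(Z @ beta, -30, 30)
            prob = expit(eta)
            w = prob * (1 - prob) + 1e-12
            grad = Z.T @ (y - prob) - pen * beta
            h = (Z * w[:, None]).T @ Z + np.diag(pen + 1e-12)
            try:
                step = np.linalg.solve(h, grad)
            except np.linalg.LinAlgError:
                return beta, False
            beta = beta + step
            if np.abs(step).max() < tol:
                return beta, True
            if np.abs(beta).max() > 40:  # separation: coefficients diverging
                return beta, False
        return beta, True

    beta, ok = _irls(ridge)
    if not ok:
        beta, _ = _irls(1e-2)  # ridge fallback under separation
    coef_std = beta[1:]
    coef = np.where(const, 0.0, coef_std / sd_safe)
    intercept = float(beta[0] - (coef * mu).sum())
    return intercept, coef


def _fit_partition_ensemble(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Imbalance-adjusted logistic fit: per-partition fits, coefficients averaged."""
    idx_min = np.flatnonzero(y == 1)
    idx_maj = np.flatnonzero(y == 0)
    plan = plan_partitions(idx_maj, idx_min, rng_seed=rng.integers(2**31))
    inters, coefs = [], []
    for k in range(plan.P):
        part = plan.partition_indices(k)
        b0, b = fit_logistic(X[part], y[part])
        inters.append(b0)
        coefs.append(b)
    return float(np.mean(inters)), np.mean(coefs, axis=0)


# ---------------------------------------------------------------------------
# feature-set reduction


@dataclass(frozen=True)
class ReducedFeatureSet:
    """Ordered reduced feature list with the Gain score of each pick."""

    names: tuple[str, ...]
    gains: tuple[float, ...]

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate features in reduced set")

    def __len__(self):
        return len(self.names)

    def rank(self, name: str) -> int:
        return self.names.index(name)


def reduce_feature_set(
    table: pd.DataFrame,
    outcome,
    target_size: int = 25,
    w_gain: float = 0.5,
    redundancy: str = "mean",
    prescreen: int | None = None,
) -> ReducedFeatureSet:
    """Greedy forward reduction balancing predictive power and non-redundancy.

    The first feature maximizes |rho_s(f, y)|; each subsequent pick maximizes
    Gain(f | S) = w_gain * |rho_s(f, y)| + (1 - w_gain) * (1 - R(f, S)) where
    R aggregates (mean or max) the MIC between f and the already-selected
    features.  ``prescreen`` optionally keeps only the top-k candidates by
    |rho_s| before the quadratic MIC pass (a pure scale control for very wide
    batteries; None searches all candidates).
    """
    if redundancy not in ("mean", "max"):
        raise ValueError("redundancy must be 'mean' or 'max'")
    y = np.asarray(outcome, dtype=float)
    X = table
    names = list(X.columns)
    r_abs = {f: abs(spearman(X[f].to_numpy(), y).rho) for f in names}
    if prescreen is not None and prescreen < len(names):
        names = sorted(names, key=lambda f: (-r_abs[f], X.columns.get_loc(f)))[:prescreen]
        names = [c for c in X.columns if c in set(names)]  # restore column order
    if len(names) < target_size:
        warnings.warn(
            f"only {len(names)} candidate features for target size {target_size}",
            stacklevel=2,
        )
        target_size = len(names)

    cols = {f: X[f].to_numpy(dtype=float) for f in names}
    mic_cache: dict[tuple[str, str], float] = {}

    def _mic(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in mic_cache:
            mic_cache[key] = mic(cols[a], cols[b])
        return mic_cache[key]

    first = max(names, key=lambda f: (r_abs[f], -names.index(f)))
    selected = [first]
    gains = [r_abs[first]]
    remaining = [f for f in names if f != first]
    red_acc = {f: 0.0 for f in remaining}  # running sum (mean) or max of MICs
    while len(selected) < target_size:
        last = selected[-1]
        best_f, best_gain = None, -np.inf
        for f in remaining:
            m = _mic(f, last)
            if redundancy == "mean":
                red_acc[f] += m
                red = red_acc[f] / len(selected)
            else:
                red_acc[f] = max(red_acc[f], m)
                red = red_acc[f]
            gain = w_gain * r_abs[f] + (1.0 - w_gain) * (1.0 - red)
            if gain > best_gain + 1e-15:
                best_f, best_gain = f, gain
        selected.append(best_f)
        gains.append(best_gain)
        remaining.remove(best_f)
    return ReducedFeatureSet(tuple(selected), tuple(gains))


# ---------------------------------------------------------------------------
# 0.632+ bootstrap AUC


class B632Result(NamedTuple):
    estimate: float
    auc_app: float
    auc_oob: float
    per_boot: np.ndarray

    @property
    def se(self) -> float:
        k = self.per_boot.size
        return float(self.per_boot.std(ddof=1) / np.sqrt(k)) if k > 1 else 0.0


def combine_632plus(auc_app: float, auc_oob: float) -> float:
    """The 0.632+ combination of apparent and out-of-bag AUC.

    R = (app - max(oob, 0.5)) / (app - 0.5), clipped to [0, 1];
    w = 0.632 / (1 - 0.368 R); estimate = (1 - w) app + w max(oob, 0.5).
    """
    oob_prime = max(auc_oob, 0.5)
    denom = auc_app - 0.5
    if denom <= 0:
        r = 0.0
    else:
        r = (auc_app - oob_prime) / denom
    r = float(np.clip(r, 0.0, 1.0))
    w = 0.632 / (1.0 - 0.368 * r)
    return float((1.0 - w) * auc_app + w * oob_prime)


def _stratified_bootstrap(y: np.ndarray, rng: np.random.Generator, max_retry: int = 10):
    """Class-stratified bootstrap indices plus the out-of-bag complement."""
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    for _ in range(max_retry):
        boot = np.concatenate(
            [rng.choice(idx1, size=idx1.size), rng.choice(idx0, size=idx0.size)]
        )
        oob = np.setdiff1d(np.arange(y.size), boot)
        if oob.size and y[oob].min() == 0 and y[oob].max() == 1:
            return boot, oob
    raise RuntimeError("could not draw a bootstrap with a two-class out-of-bag set")


def _as_xy(table, features: Sequence[str], outcome):
    df = table.df if hasattr(table, "df") else table
    df = df.sort_index()  # row-order invariance: resampling keyed to sorted ids
    if isinstance(outcome, str):
        y = df[outcome].to_numpy(dtype=int)
    else:
        y = pd.Series(np.asarray(outcome), index=(table.df if hasattr(table, "df") else table).index)
        y = y.sort_index().to_numpy(dtype=int)
    X = df[list(features)].to_numpy(dtype=float)
    return X, y


def auc_632plus(
    features: Sequence[str],
    table,
    outcome="event",
    n_boot: int = 100,
    rng_seed=None,
) -> B632Result:
    """0.632+ bootstrap AUC of an imbalance-adjusted logistic model."""
    X, y = _as_xy(table, features, outcome)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 events and 2 non-events")
    rng = np.random.default_rng(rng_seed)
    b0, b = _fit_partition_ensemble(X, y, rng)
    auc_app = auc_mann_whitney(X @ b + b0, y)
    per_boot = []
    for _ in range(n_boot):
        boot, oob = _stratified_bootstrap(y, rng)
        bb0, bb = _fit_partition_ensemble(X[boot], y[boot], rng)
        per_boot.append(auc_mann_whitney(X[oob] @ bb + bb0, y[oob]))
    per_boot = np.asarray(per_boot)
    auc_oob = float(per_boot.mean())
    return B632Result(combine_632plus(auc_app, auc_oob), auc_app, auc_oob, per_boot)


# ---------------------------------------------------------------------------
# forward selection and order choice


@dataclass(frozen=True)
class OrderModel:
    order: int
    features: tuple[str, ...]
    estimate: float
    se: float


def forward_select(
    reduced: ReducedFeatureSet,
    table,
    outcome="event",
    orders: int = 10,
    n_boot: int = 100,
    rng_seed=None,
) -> list[OrderModel]:
    """Greedy forward selection over the reduced set, one model per order.

    The order-k model extends the best order-(k-1) model with the candidate
    maximizing the 0.632+ AUC; ties break by reduced-set rank.
    """
    rng = np.random.default_rng(rng_seed)
    avail = list(reduced.names)
    if orders > len(avail):
        warnings.warn(
            f"requested {orders} orders but only {len(avail)} features; truncating",
            stacklevel=2,
        )
        orders = len(avail)
    current: list[str] = []
    out: list[OrderModel] = []
    for k in range(1, orders + 1):
        best: tuple[float, int, str, B632Result] | None = None
        seed_k = rng.integers(2**31)
        for f in avail:
            res = auc_632plus(current + [f], table, outcome, n_boot, rng_seed=seed_k)
            key = (res.estimate, -reduced.rank(f))
            if best is None or key > best[:2]:
                best = (res.estimate, -reduced.rank(f), f, res)
        _, _, f, res = best
        current.append(f)
        avail.remove(f)
        out.append(OrderModel(k, tuple(current), res.estimate, res.se))
    return out


def choose_order(models: Sequence[OrderModel]) -> OrderModel:
    """Parsimony rule: smallest order whose estimate is within one standard
    error of the best estimate (manual override: just pick from the list)."""
    best = max(models, key=lambda m: m.estimate)
    thr = best.estimate - best.se
    for m in sorted(models, key=lambda m: m.order):
        if m.estimate >= thr:
            return m
    return best


# ---------------------------------------------------------------------------
# final model


@dataclass(frozen=True)
class LogisticModel:
    """Bootstrap-averaged logistic risk model (predicts event probability)."""

    features: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    n_boot: int = 0
    rng_seed: int | None = None

    def __post_init__(self):
        if not 1 <= len(self.features):
            raise ValueError("model needs at least one feature")
        if not np.isfinite(self.coefficients).all() or not np.isfinite(self.intercept):
            raise ValueError("non-finite coefficients")

    def linear_predictor(self, table) -> np.ndarray:
        df = table.df if hasattr(table, "df") else table
        X = df[list(self.features)].to_numpy(dtype=float)
        return X @ self.coefficients + self.intercept

    def predict_proba(self, table) -> np.ndarray:
        return expit(self.linear_predictor(table))

    def to_json(self) -> str:
        return json.dumps(
            {
                "features": list(self.features),
                "coefficients": self.coefficients.tolist(),
                "intercept": self.intercept,
                "n_boot": self.n_boot,
                "rng_seed": self.rng_seed,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "LogisticModel":
        d = json.loads(s)
        return cls(
            tuple(d["features"]),
            np.asarray(d["coefficients"], dtype=float),
            float(d["intercept"]),
            d.get("n_boot", 0),
            d.get("rng_seed"),
        )


def finalize_logistic(
    features: Sequence[str],
    table,
    outcome="event",
    n_boot: int = 100,
    rng_seed=None,
) -> LogisticModel:
    """Final coefficients: partition-ensemble fits averaged over bootstraps.

    ``n_boot=1`` is a degenerate no-resampling mode fitting the full sample
    once (with a balanced sample and P = 1 this equals a plain logistic fit).
    """
    df = table.df if hasattr(table, "df") else table
    X, y = _as_xy(table, features, outcome)
    const = X.std(axis=0) == 0
    if const.any():
        bad = [f for f, c in zip(features, const) if c]
        warnings.warn(f"zero-variance features get coefficient 0: {bad}", stacklevel=2)
    rng = np.random.default_rng(rng_seed)
    inters, coefs = [], []
    if n_boot == 1:
        b0, b = _fit_partition_ensemble(X, y, rng)
        inters.append(b0)
        coefs.append(b)
    else:
        for _ in range(n_boot):
            boot, _ = _stratified_bootstrap(y, rng)
            b0, b = _fit_partition_ensemble(X[boot], y[boot], rng)
            inters.append(b0)
            coefs.append(b)
    coef = np.mean(coefs, axis=0)
    coef[const] = 0.0
    seed_val = int(rng_seed) if isinstance(rng_seed, (int, np.integer)) else None
    return LogisticModel(tuple(features), coef, float(np.mean(inters)), n_boot, seed_val)
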