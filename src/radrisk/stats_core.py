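"""Statistical primitives: rank correlation, FDR control, ROC metrics,
DeLong AUC comparison, Harrell's concordance index and Kaplan-Meier/log-rank.

Thin, well-specified wrappers: scipy/statsmodels/lifelines provide the
standard machinery; the hand-rolled pieces (midrank AUC, DeLong covariance,
permissible-pair concordance) are here because the modelling loops call them
at high frequency and the exact tie conventions matter.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mic import mic  # re-exported: MIC lives in its own submodule

__all__ = [
    "AssociationResult",
    "SurvivalData",
    "SpearmanResult",
    "spearman",
    "benjamini_hochberg",
    "mic",
    "roc_metrics",
    "delong_test",
    "concordance_index",
    "km_logrank",
    "univariate_screen",
]


@dataclass(frozen=True)
class SurvivalData:
    """Per-subject follow-up time (months) and event indicator."""

    time_months: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time_months, dtype=float)
        e = np.asarray(self.event, dtype=int)
        if t.shape != e.shape:
            raise ValueError("time and event shapes differ")
        if not np.isfinite(t).all() or (t < 0).any():
            raise ValueError("times must be finite and non-negative")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("event must be 0/1")
        object.__setattr__(self, "time_months", t)
        object.__setattr__(self, "event", e)

    def __len__(self):
        return self.time_months.size


@dataclass(frozen=True)
class AssociationResult:
    feature_name: str
    r_s: float
    p_value: float
    significant_after_fdr: bool = False


class SpearmanResult(NamedTuple):
    rho: float
    p: float
    degenerate: bool = False


def spearman(x, y, exact_below: int = 9) -> SpearmanResult:
    """Spearman rank correlation with midranks for ties.

    p-values use the t approximation; for very small samples (n < 9, no
    approximation headroom) the exact permutation distribution is enumerated.
    Constant input is degenerate: returns rho = 0, p = 1, flagged.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(0.0, 1.0, True)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n < exact_below:
        obs = abs(rho)
        count = 0
        total = 0
        rxc = rx - rx.mean()
        denom_x = np.sqrt((rxc**2).sum())
        for perm in itertools.permutations(range(n)):
            ryp = ry[list(perm)]
            ryc = ryp - ryp.mean()
            r = float(rxc @ ryc) / (denom_x * np.sqrt((ryc**2).sum()))
            total += 1
            if abs(r) >= obs - 1e-12:
                count += 1
        return SpearmanResult(rho, count / total)
    if abs(rho) >= 1.0:
        return SpearmanResult(rho, 0.0)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return SpearmanResult(rho, float(min(p, 1.0)))


def benjamini_hochberg(p: Sequence[float], q: float = 0.10) -> np.ndarray:
    """Step-up FDR control: boolean flags of the rejected hypotheses."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def univariate_screen(features: pd.DataFrame, outcome, q: float = 0.10) -> list[AssociationResult]:
    """Spearman screen of every feature column against a binary outcome,
    with Benjamini-Hochberg correction at FDR ``q``."""
    y = np.asarray(outcome, dtype=float)
    results = []
    for name in features.columns:
        r = spearman(features[name].to_numpy(), y)
        results.append(AssociationResult(name, r.rho, r.p))
    flags = benjamini_hochberg([r.p_value for r in results], q)
    return [
        AssociationResult(r.feature_name, r.r_s, r.p_value, bool(f))
        for r, f in zip(results, flags)
    ]


# ---------------------------------------------------------------------------
# ROC


class RocMetrics(NamedTuple):
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney U statistic scaled to [0, 1]; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = sps.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_metrics(scores, labels, threshold: float = 0.5) -> RocMetrics:
    """AUC plus sensitivity/specificity/accuracy at a probability threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc = auc_mann_whitney(scores, labels)
    pred = scores > threshold
    pos = labels == 1
    sens = float(pred[pos].mean())
    spec = float((~pred[~pos]).mean())
    acc = float((pred == pos).mean())
    return RocMetrics(auc, sens, spec, acc)


# ---------------------------------------------------------------------------
# DeLong


def _midrank(v: np.ndarray) -> np.ndarray:
    return sps.rankdata(v, method="average")


def _delong_structural(scores: np.ndarray, labels: np.ndarray):
    """Per-subject structural components V10 (cases) and V01 (controls)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


def delong_test(scores_a, scores_b, labels) -> float:
    """Two-sided p-value for the difference of two paired AUCs (DeLong)."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired scores must share the subjects")
    auc_a, v10_a, v01_a = _delong_structural(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_structural(scores_b, labels)
    m = v10_a.size
    n = v01_a.size
    s10 = np.cov(np.stack([v10_a, v10_b]), bias=False)
    s01 = np.cov(np.stack([v01_a, v01_b]), bias=False)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 1e-15:
        return 1.0
    z = (auc_a - auc_b) / math.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# survival


def concordance_index(risk_scores, survival: SurvivalData) -> float:
    """Harrell's concordance index between risk scores and time-to-event.

    A pair is permissible when the shorter observed time carries an event
    (tied times are not permissible); the pair is concordant when the subject
    failing earlier has the higher risk score; score ties count 1/2.
    """
    r = np.asarray(risk_scores, dtype=float)
    t = survival.time_months
    e = survival.event
    ti, tj = t[:, None], t[None, :]
    ei = e[:, None]
    perm = (ti < tj) & (ei == 1)
    n_perm = int(perm.sum())
    if n_perm == 0:
        raise ValueError("no permissible pairs (need an event before another time)")
    ri, rj = r[:, None], r[None, :]
    conc = (perm & (ri > rj)).sum() + 0.5 * (perm & (ri == rj)).sum()
    return float(conc / n_perm)


@dataclass(frozen=True)
class KMResult:
    """Product-limit curves per group, log-rank statistic, and p-values."""

    curves: dict
    statistic: float
    p_value: float
    pairwise: dict = field(default_factory=dict)


def km_logrank(groups, survival: SurvivalData) -> KMResult:
    """Kaplan-Meier curves and the log-rank test across >= 2 groups.

    For more than two groups the global G-1 df test is returned along with
    unadjusted pairwise comparisons.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test, multivariate_logrank_test

    g = np.asarray(groups)
    t = survival.time_months
    e = survival.event
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for lab in labels:
        if (g == lab).sum() == 0:
            raise ValueError(f"group {lab!r} is empty")
    if e.sum() == 0:
        raise ValueError("log-rank requires at least one event")

    curves = {}
    for lab in labels:
        sel = g == lab
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel], label=str(lab))
        curves[lab] = kmf

    res = multivariate_logrank_test(t, g, e)
    pairwise = {}
    if len(labels) > 2:
        for a, b in itertools.combinations(labels, 2):
            sel_a, sel_b = g == a, g == b
            lr = logrank_test(t[sel_a], t[sel_b], e[sel_a], e[sel_b])
            pairwise[(a, b)] = float(lr.p_value)
    return KMResult(curves, float(res.test_statistic), float(res.p_value), pairwise)
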