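"""Synthetic fixtures with known ground truth.

Two generators:

* textured 3D phantoms — Gaussian-smoothed white noise inside an ellipsoidal
  ROI on a regular grid, with the heterogeneity scale set by the smoothing
  correlation length (SUV-like or HU-like value ranges via the spec);
* imbalanced cohorts — feature tables with a known generative logistic model
  for the binary event, exponential time-to-event accelerated by the linear
  risk, and independent exponential censoring of event-free follow-up.

Defaults mirror the study conditions the package targets: event rates of
10-20%, cohorts of a few hundred subjects, censored follow-up over ~5 years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.special import expit

from .feature_bank import FeatureTable
from .forest_models import HN_TYPES
from .image_core import ImageVolume, ROIMask

__all__ = ["PhantomSpec", "CohortSpec", "make_phantom", "make_cohort"]


@dataclass(frozen=True)
class PhantomSpec:
    """Textured ellipsoid phantom specification.

    ``texture_corr_mm`` is the Gaussian smoothing length of the noise field:
    0 gives voxel-wise white noise, larger values give coarser, blob-like
    heterogeneity (fewer, larger iso-intensity zones).
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    roi_axes_mm: tuple[float, float, float] = (10.0, 10.0, 10.0)
    texture_mean: float = 5.0
    texture_variance: float = 2.0
    texture_corr_mm: float = 2.0
    background_mean: float = 0.5
    modality: str = "PET"
    rng_seed: int = 0

    def __post_init__(self):
        if self.texture_variance < 0 or self.texture_corr_mm < 0:
            raise ValueError("variance and correlation length must be >= 0")


def make_phantom(spec: PhantomSpec) -> tuple[ImageVolume, ROIMask]:
    """Build one phantom volume and its ellipsoidal ROI mask."""
    shape = tuple(spec.shape)
    sp = np.asarray(spec.spacing, dtype=float)
    half_extent = np.asarray(shape) * sp / 2.0
    axes = np.asarray(spec.roi_axes_mm, dtype=float)
    if (axes >= half_extent).any():
        raise ValueError(
            f"ROI semi-axes {tuple(axes)} mm do not fit the grid half-extent "
            f"{tuple(half_extent)} mm"
        )
    rng = np.random.default_rng(spec.rng_seed)
    coords = [
        (np.arange(n) + 0.5) * s - n * s / 2.0 for n, s in zip(shape, sp)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    mask = (xx / axes[0]) ** 2 + (yy / axes[1]) ** 2 + (zz / axes[2]) ** 2 <= 1.0

    noise = rng.standard_normal(shape)
    if spec.texture_corr_mm > 0:
        sigma_vox = spec.texture_corr_mm / sp
        noise = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    if spec.texture_variance > 0:
        sd = noise.std()
        field = noise / (sd if sd > 0 else 1.0) * np.sqrt(spec.texture_variance)
    else:
        field = np.zeros(shape)

    data = np.full(shape, float(spec.background_mean))
    data[mask] = spec.texture_mean + field[mask]
    return (
        ImageVolume(data, tuple(sp), spec.modality),
        ROIMask(mask, tuple(sp)),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Imbalanced cohort with a known generative logistic risk model.

    ``coefficients`` maps feature names to logistic log-odds slopes on the
    standardized feature scale; recognised clinical names (age, hn_type,
    t_stage, n_stage, tnm_stage) are generated with realistic marginals,
    anything else is standard normal.  The intercept is calibrated so the
    expected event proportion equals ``event_rate``.  Event times are
    exponential with log-hazard proportional to the same linear risk;
    event-free follow-up is censored by an independent exponential calibrated
    to ``censoring_rate``.
    """

    n: int = 200
    event_rate: float = 0.15
    coefficients: dict = field(default_factory=lambda: {"f1": 2.0, "f2": 1.5, "f3": 1.0})
    n_noise: int = 0
    include_clinical: bool = False
    follow_up_months: float = 60.0
    baseline_hazard: float = 0.03
    log_hr_per_unit: float = 0.7
    censoring_rate: float = 0.2
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.event_rate < 1:
            raise ValueError("event_rate must lie in (0, 1)")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")


_CLINICAL = ("age", "hn_type", "t_stage", "n_stage", "tnm_stage")


def _gen_clinical(n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = np.clip(rng.normal(62, 10, n), 25, 90)
    hn = rng.choice(HN_TYPES, size=n, p=[0.5, 0.15, 0.15, 0.2])
    t = rng.integers(1, 5, n)
    nn = rng.integers(0, 4, n)
    tnm = np.clip(np.maximum(t, nn + 1), 1, 4)
    return pd.DataFrame(
        {"age": age, "hn_type": hn, "t_stage": t, "n_stage": nn, "tnm_stage": tnm}
    )


def _numeric_codes(df: pd.DataFrame, name: str) -> np.ndarray:
    """Standardized numeric encoding of a column for the generative risk."""
    if name == "hn_type":
        v = np.asarray([HN_TYPES.index(h) for h in df[name]], dtype=float)
    else:
        v = df[name].to_numpy(dtype=float)
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def make_cohort(spec: CohortSpec) -> FeatureTable:
    """Generate one cohort table with features and outcome columns."""
    rng = np.random.default_rng(spec.rng_seed)
    for attempt in range(2):
        df = _draw(spec, rng)
        if df["event"].sum() > 0:
            return FeatureTable(df)
    raise ValueError("cohort realized zero events twice; raise n or event_rate")


def _draw(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n
    cols: dict[str, np.ndarray] = {}
    clinical = None
    need_clinical = spec.include_clinical or any(
        f in _CLINICAL for f in spec.coefficients
    )
    if need_clinical:
        clinical = _gen_clinical(n, rng)
        for c in clinical.columns:
            cols[c] = clinical[c].to_numpy()
    for name in spec.coefficients:
        if name not in cols:
            cols[name] = rng.standard_normal(n)
    for k in range(spec.n_noise):
        cols[f"noise{k:03d}"] = rng.standard_normal(n)

    df = pd.DataFrame(cols)
    risk = np.zeros(n)
    for name, beta in spec.coefficients.items():
        if name in _CLINICAL:
            risk += beta * _numeric_codes(df, name)
        else:
            risk += beta * df[name].to_numpy(dtype=float)

    # intercept calibrated so the expected event proportion matches the spec
    c = optimize.brentq(
        lambda c0: expit(c0 + risk).mean() - spec.event_rate, -30, 30
    )
    p_event = expit(c + risk)
    event = (rng.random(n) < p_event).astype(int)

    hazard = spec.baseline_hazard * np.exp(spec.log_hr_per_unit * (risk - risk.mean()))
    t_event = rng.exponential(1.0 / hazard)
    fu = spec.follow_up_months
    time = np.where(event == 1, np.minimum(t_event, fu), fu)
    censored = np.zeros(n, dtype=int)
    if spec.censoring_rate > 0:
        lam_c = -np.log(1.0 - spec.censoring_rate) / fu
        t_cens = rng.exponential(1.0 / lam_c, size=n)
        cut = (event == 0) & (t_cens < fu)
        censored[cut] = 1
        time = np.where(cut, t_cens, time)

    df["event"] = event
    df["time_months"] = np.round(time, 3)
    df["censored"] = censored
    df.index = pd.Index([f"P{i:04d}" for i in range(n)], name="patient_id")
    return df
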