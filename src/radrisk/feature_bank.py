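"""The per-modality radiomic feature battery.

1615 features per scan: 10 first-order intensity statistics, 5 morphological
(shape) features, and 40 texture features computed at each of the 40 points of
the extraction-parameter grid (5 isotropic voxel sizes x 2 quantization
algorithms x 4 gray-level counts), i.e. 10 + 5 + 40*40.

Intensity and shape are computed once at native resolution; textures are
computed after isotropic resampling and within-ROI quantization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image_core import (
    ImageVolume,
    ROIMask,
    QuantizedROI,
    enumerate_texture_grid,
    quantize,
    resample_isotropic,
)
from .texture_matrices import (
    GLCM,
    GLRLM,
    GLSZM,
    NGTDM,
    build_glcm,
    build_glrlm,
    build_glszm,
    build_ngtdm,
)

__all__ = [
    "FeatureVector",
    "FeatureTable",
    "intensity_features",
    "shape_features",
    "texture_features",
    "extract_battery",
    "texture_feature_names",
    "battery_feature_names",
    "N_FEATURES",
]

EPS = 1e-9

INTENSITY_NAMES = (
    "variance",
    "skewness",
    "kurtosis",
    "SUVmax",
    "SUVpeak",
    "SUVmean",
    "aucCSH",
    "TLG",
    "pct_inactive",
    "gETU",
)
SHAPE_NAMES = ("volume", "size", "solidity", "eccentricity", "compactness")
GLCM_NAMES = (
    "Energy",
    "Contrast",
    "Entropy",
    "Homogeneity",
    "Correlation",
    "SumAverage",
    "Variance",
    "Dissimilarity",
    "AutoCorrelation",
)
GLRLM_NAMES = (
    "SRE",
    "LRE",
    "GLN",
    "RLN",
    "RP",
    "LGRE",
    "HGRE",
    "SRLGE",
    "SRHGE",
    "LRLGE",
    "LRHGE",
    "GLV",
    "RLV",
)
GLSZM_NAMES = (
    "SZE",
    "LZE",
    "GLN",
    "ZSN",
    "ZP",
    "LGZE",
    "HGZE",
    "SZLGE",
    "SZHGE",
    "LZLGE",
    "LZHGE",
    "GLV",
    "ZSV",
)
NGTDM_NAMES = ("Coarseness", "Busyness", "Contrast", "Complexity", "Strength")

N_FEATURES = 10 + 5 + 40 * 40


@dataclass(frozen=True)
class FeatureVector:
    """All 1615 named radiomic features of one scan."""

    values: dict[str, float]
    modality: str

    def __post_init__(self):
        if len(self.values) != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} features, got {len(self.values)}")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, dtype=float)


# ---------------------------------------------------------------------------
# intensity


def intensity_features(
    vol: ImageVolume,
    mask: ROIMask,
    n_bins: int = 100,
    inactive_frac: float = 0.5,
    getu_a: float = 1.0,
) -> dict[str, float]:
    """10 first-order intensity statistics of the ROI.

    Moments are computed from the raw voxel values; the cumulative
    intensity-volume histogram (aucCSH) uses ``n_bins`` thresholds spanning
    the ROI intensity range.  ``pct_inactive`` is the fraction of the ROI
    below ``inactive_frac`` of the maximum; gETU generalizes total lesion
    glycolysis with exponent ``getu_a`` (a = 1 reduces to TLG).
    """
    x = vol.data[mask.data].astype(float)
    n = x.size
    vol_cm3 = mask.n_voxels * vol.voxel_volume_mm3 / 1000.0
    mean = float(x.mean())
    xc = x - mean
    m2 = float(np.mean(xc**2))
    # guard: rounding noise on a constant ROI must not fabricate moments
    if n < 2 or m2 <= (1e-12 * max(1.0, abs(mean))) ** 2:
        var = skew = kurt = 0.0
    else:
        var = m2
        m3 = float(np.mean(xc**3))
        m4 = float(np.mean(xc**4))
        skew = m3 / m2**1.5
        kurt = m4 / m2**2  # Pearson (non-excess) kurtosis

    vmax = float(x.max())
    vmin = float(x.min())

    # SUVpeak: mean over in-ROI voxels within a 1 cm^3 sphere centred on the max voxel
    peak = _suv_peak(vol, mask)

    # aucCSH: area under fractional-volume-above-threshold vs normalized threshold
    if vmax == vmin:
        auc_csh = 1.0
    else:
        thresholds = vmin + (vmax - vmin) * np.arange(n_bins) / n_bins
        frac_above = (x[None, :] >= thresholds[:, None]).mean(axis=1)
        auc_csh = float(frac_above.mean())

    tlg = mean * vol_cm3
    pct_inactive = float((x < inactive_frac * vmax).mean())
    if getu_a == 1.0:
        getu = tlg
    else:
        getu = vol_cm3 * float(np.mean(np.clip(x, 0, None) ** getu_a)) ** (1.0 / getu_a)

    return {
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "SUVmax": vmax,
        "SUVpeak": peak,
        "SUVmean": mean,
        "aucCSH": auc_csh,
        "TLG": tlg,
        "pct_inactive": pct_inactive,
        "gETU": getu,
    }


def _suv_peak(vol: ImageVolume, mask: ROIMask, sphere_cm3: float = 1.0) -> float:
    radius = (3.0 * sphere_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)  # mm
    x = vol.data[mask.data]
    imax_flat = int(np.argmax(x))
    centers = np.argwhere(mask.data) * np.asarray(vol.spacing)
    cmax = centers[imax_flat]
    dist = np.linalg.norm(centers - cmax, axis=1)
    return float(x[dist <= radius].mean())


# ---------------------------------------------------------------------------
# shape


def shape_features(mask: ROIMask, spacing=None) -> dict[str, float]:
    """5 morphological features: volume (cm^3), size (max diameter, mm),
    solidity, eccentricity and compactness.

    Compactness is V / (sqrt(pi) * A^(3/2)) with the surface area A taken from
    a marching-cubes mesh of the mask (the smooth-sphere value is 1/(6*pi)).
    Eccentricity comes from the principal axes of the voxel-centre second
    moments; solidity is the ROI voxel count over the voxel count of its
    convex hull.
    """
    sp = np.asarray(spacing if spacing is not None else mask.spacing, dtype=float)
    n = mask.n_voxels
    voxvol = float(np.prod(sp))
    volume_cm3 = n * voxvol / 1000.0

    centers = np.argwhere(mask.data) * sp
    size = _max_diameter(centers)
    solidity = _solidity(mask.data, sp)
    eccentricity = _eccentricity(centers)
    compactness = _compactness(mask.data, sp, n * voxvol)

    return {
        "volume": volume_cm3,
        "size": size,
        "solidity": solidity,
        "eccentricity": eccentricity,
        "compactness": compactness,
    }


def _max_diameter(centers: np.ndarray) -> float:
    if len(centers) == 1:
        return 0.0
    pts = centers
    if len(pts) > 300:
        try:
            from scipy.spatial import ConvexHull

            pts = centers[ConvexHull(centers).vertices]
        except Exception:  # degenerate geometry: fall back to all points
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _solidity(mask: np.ndarray, sp: np.ndarray) -> float:
    from scipy.spatial import Delaunay, QhullError

    centers = np.argwhere(mask)
    if len(centers) < 5:
        return 1.0
    try:
        hull = Delaunay(centers * sp)
    except QhullError:  # coplanar / collinear ROI
        return 1.0
    lo = centers.min(axis=0)
    hi = centers.max(axis=0)
    grid = np.stack(
        np.meshgrid(*[np.arange(lo[a], hi[a] + 1) for a in range(3)], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    inside = hull.find_simplex(grid * sp) >= 0
    n_hull = int(inside.sum())
    return float(len(centers) / max(n_hull, len(centers)))


def _eccentricity(centers: np.ndarray) -> float:
    if len(centers) < 2:
        return 0.0
    cov = np.cov(centers.T, bias=True)
    lam = np.linalg.eigvalsh(cov)
    lam = np.clip(lam, 0, None)
    if lam[-1] <= 0:
        return 0.0
    return float(np.sqrt(1.0 - lam[0] / lam[-1]))


def _compactness(mask: np.ndarray, sp: np.ndarray, volume_mm3: float) -> float:
    from scipy import ndimage
    from skimage import measure

    padded = np.pad(mask.astype(float), 2)
    # light smoothing before meshing suppresses the voxel staircase, which
    # otherwise inflates the area of curved surfaces by ~9%; thin ROIs whose
    # smoothed peak would drop below the iso-level keep the binary mesh
    smoothed = ndimage.gaussian_filter(padded, 0.8)
    if smoothed.max() > 0.5:
        padded = smoothed
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(sp))
    area = measure.mesh_surface_area(verts, faces)
    return float(volume_mm3 / (np.sqrt(np.pi) * area**1.5))


# ---------------------------------------------------------------------------
# texture features


def texture_feature_names() -> list[str]:
    """The 40 texture feature names with family suffixes (9+13+13+5)."""
    return (
        [f"{f}_GLCM" for f in GLCM_NAMES]
        + [f"{f}_GLRLM" for f in GLRLM_NAMES]
        + [f"{f}_GLSZM" for f in GLSZM_NAMES]
        + [f"{f}_NGTDM" for f in NGTDM_NAMES]
    )


def glcm_features(glcm: GLCM) -> dict[str, float]:
    g = glcm.n_gray
    if glcm.degenerate:
        solo = glcm.solo_level or 1
        vals = dict.fromkeys(GLCM_NAMES, 0.0)
        vals.update(
            Energy=1.0,
            Homogeneity=1.0,
            SumAverage=2.0 * solo,
            AutoCorrelation=float(solo**2),
        )
        return {f"{k}_GLCM": float(vals[k]) for k in GLCM_NAMES}
    p = glcm.m
    i = np.arange(1, g + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    pi = p.sum(axis=1)
    mu = float((i * pi).sum())
    sig2 = float(((i - mu) ** 2 * pi).sum())
    nz = p > 0
    autocorr = float((I * J * p).sum())
    corr = (autocorr - mu * mu) / sig2 if sig2 > 0 else 0.0
    return {
        "Energy_GLCM": float((p**2).sum()),
        "Contrast_GLCM": float(((I - J) ** 2 * p).sum()),
        "Entropy_GLCM": float(-(p[nz] * np.log2(p[nz])).sum()),
        "Homogeneity_GLCM": float((p / (1.0 + np.abs(I - J))).sum()),
        "Correlation_GLCM": float(corr),
        "SumAverage_GLCM": float(((I + J) * p).sum()),
        "Variance_GLCM": sig2,
        "Dissimilarity_GLCM": float((np.abs(I - J) * p).sum()),
        "AutoCorrelation_GLCM": autocorr,
    }


def _run_zone_features(m: np.ndarray, names: tuple[str, ...], family: str) -> dict[str, float]:
    """Shared 13-feature battery of the run-length and size-zone matrices."""
    g_dim, l_dim = m.shape
    gi = np.arange(1, g_dim + 1)[:, None].astype(float)
    li = np.arange(1, l_dim + 1)[None, :].astype(float)
    total = m.sum()
    if total <= 0:
        return {f"{n}_{family}": 0.0 for n in names}
    coverage = float((m * li).sum())
    pn = m / total
    mu_g = float((pn * gi).sum())
    mu_l = float((pn * li).sum())
    feats = {
        names[0]: float((m / li**2).sum() / total),          # SRE / SZE
        names[1]: float((m * li**2).sum() / total),          # LRE / LZE
        names[2]: float((m.sum(axis=1) ** 2).sum() / total),  # GLN
        names[3]: float((m.sum(axis=0) ** 2).sum() / total),  # RLN / ZSN
        names[4]: float(total / coverage),                    # RP / ZP
        names[5]: float((m / gi**2).sum() / total),           # LGRE / LGZE
        names[6]: float((m * gi**2).sum() / total),           # HGRE / HGZE
        names[7]: float((m / (gi**2 * li**2)).sum() / total),  # SRLGE / SZLGE
        names[8]: float((m * gi**2 / li**2).sum() / total),   # SRHGE / SZHGE
        names[9]: float((m * li**2 / gi**2).sum() / total),   # LRLGE / LZLGE
        names[10]: float((m * gi**2 * li**2).sum() / total),  # LRHGE / LZHGE
        names[11]: float((pn * (gi - mu_g) ** 2).sum()),      # GLV
        names[12]: float((pn * (li - mu_l) ** 2).sum()),      # RLV / ZSV
    }
    return {f"{n}_{family}": v for n, v in feats.items()}


def glrlm_features(glrlm: GLRLM) -> dict[str, float]:
    return _run_zone_features(glrlm.m, GLRLM_NAMES, "GLRLM")


def glszm_features(glszm: GLSZM) -> dict[str, float]:
    return _run_zone_features(glszm.m, GLSZM_NAMES, "GLSZM")


def ngtdm_features(ngtdm: NGTDM) -> dict[str, float]:
    s, p, n = ngtdm.s, ngtdm.p, ngtdm.n_counted
    g = ngtdm.n_gray
    i = np.arange(1, g + 1, dtype=float)
    occ = p > 0
    na = int(occ.sum())
    coarseness = 1.0 / (EPS + float((p * s).sum()))
    if na < 2 or n == 0:
        contrast = busyness = complexity = strength = 0.0
    else:
        io, po, so = i[occ], p[occ], s[occ]
        dif2 = (io[:, None] - io[None, :]) ** 2
        contrast = float(
            (po[:, None] * po[None, :] * dif2).sum() / (na * (na - 1)) * (s.sum() / n)
        )
        denom = np.abs(io[:, None] * po[:, None] - io[None, :] * po[None, :]).sum()
        busyness = float((po * so).sum() / denom) if denom > 0 else 0.0
        complexity = float(
            (
                np.abs(io[:, None] - io[None, :])
                * (po[:, None] * so[:, None] + po[None, :] * so[None, :])
                / (n * (po[:, None] + po[None, :]))
            ).sum()
        )
        strength = float(
            ((po[:, None] + po[None, :]) * dif2).sum() / (EPS + s.sum())
        )
    vals = {
        "Coarseness": coarseness,
        "Busyness": busyness,
        "Contrast": contrast,
        "Complexity": complexity,
        "Strength": strength,
    }
    return {f"{k}_NGTDM": float(vals[k]) for k in NGTDM_NAMES}


def texture_features(
    q: QuantizedROI,
    glcm: GLCM | None = None,
    glrlm: GLRLM | None = None,
    glszm: GLSZM | None = None,
    ngtdm: NGTDM | None = None,
    weighted: bool = True,
) -> dict[str, float]:
    """All 40 texture features of one quantized ROI (matrices built on demand)."""
    out: dict[str, float] = {}
    out.update(glcm_features(glcm if glcm is not None else build_glcm(q, weighted)))
    out.update(glrlm_features(glrlm if glrlm is not None else build_glrlm(q, weighted)))
    out.update(glszm_features(glszm if glszm is not None else build_glszm(q)))
    out.update(ngtdm_features(ngtdm if ngtdm is not None else build_ngtdm(q, weighted)))
    return out


# ---------------------------------------------------------------------------
# the battery


def battery_feature_names() -> list[str]:
    """Deterministic names of all 1615 features (stable lexicographic order)."""
    names = [f"intensity_{n}" for n in INTENSITY_NAMES]
    names += [f"shape_{n}" for n in SHAPE_NAMES]
    for params in enumerate_texture_grid():
        for t in texture_feature_names():
            names.append(f"{t}__{params.tag}")
    return sorted(names)


class FeatureTable:
    """Patients x named features, the currency between extraction and modelling.

    Wraps a DataFrame indexed by unique patient id.  Outcome columns, when
    present, are ``event`` (0/1), ``time_months`` (>= 0) and ``censored``
    (0/1, with event = 1 implying censored = 0).
    """

    OUTCOME_COLUMNS = ("event", "time_months", "censored")

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated patient ids: {dupes}")
        if "event" in df.columns and "censored" in df.columns:
            bad = (df["event"] == 1) & (df["censored"] == 1)
            if bad.any():
                raise ValueError(
                    f"event=1 with censored=1 for ids {df.index[bad].tolist()}"
                )
        if "time_months" in df.columns and (df["time_months"] < 0).any():
            raise ValueError("negative time_months")
        self.df = df

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in self.OUTCOME_COLUMNS]

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path, config: dict | None = None) -> None:
        """Write the table as CSV with a JSON side-car recording the config."""
        import json
        from pathlib import Path

        path = Path(path)
        self.df.to_csv(path, index_label="patient_id")
        sidecar = {"schema_version": 1, "n_rows": len(self.df), "config": config or {}}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="patient_id")
        return cls(df)


def extract_battery(
    vol: ImageVolume,
    mask: ROIMask,
    n_bins: int = 100,
    inactive_frac: float = 0.5,
    getu_a: float = 1.0,
    weighted: bool = True,
) -> FeatureVector:
    """Extract all 1615 radiomic features of one scan.

    Intensity and shape features are computed at native resolution; the 40
    texture features are recomputed at each of the 40 extraction-grid points
    (isotropic resampling + quantization), with names suffixed by the grid
    point (e.g. ``GLN_GLSZM__vx3mm_Uniform_Ng32``).
    """
    values: dict[str, float] = {}
    for k, v in intensity_features(vol, mask, n_bins, inactive_frac, getu_a).items():
        values[f"intensity_{k}"] = v
    for k, v in shape_features(mask).items():
        values[f"shape_{k}"] = v
    for params in enumerate_texture_grid():
        try:
            rvol, rmask = resample_isotropic(vol, mask, params.voxel_size_mm)
        except ValueError as exc:
            raise ValueError(
                f"texture grid point {params.tag}: {exc}"
            ) from exc
        q = quantize(rvol, rmask, params)
        for k, v in texture_features(q, weighted=weighted).items():
            values[f"{k}__{params.tag}"] = v
    ordered = {k: values[k] for k in sorted(values)}
    return FeatureVector(ordered, vol.modality)
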