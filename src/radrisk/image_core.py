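"""Image/mask ingestion, isotropic resampling and within-ROI gray-level quantization.

The tumour region of interest (ROI) is carried as a binary mask aligned with a
3D scalar volume (SUV for PET, HU for CT).  Texture analysis operates on a
resampled, quantized copy of the ROI: the volume is interpolated onto an
isotropic grid (1-5 mm) and the in-ROI intensities are discretized to a fixed
number of gray levels with either a *uniform* (equal intensity width) or an
*equal-probability* (histogram equalization) rule.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "ROIMask",
    "TextureParams",
    "QuantizedROI",
    "enumerate_texture_grid",
    "resample_isotropic",
    "quantize_uniform",
    "quantize_equalprob",
    "load_nifti_pair",
    "save_nifti",
]

VOXEL_SIZES_MM = (1.0, 2.0, 3.0, 4.0, 5.0)
QUANT_ALGOS = ("EqualProbability", "Uniform")
GRAY_LEVELS = (8, 16, 32, 64)

#: sentinel stored outside the ROI in a :class:`QuantizedROI`
OUTSIDE = 0


@dataclass(frozen=True)
class ImageVolume:
    """3D scalar image with anisotropic voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: Literal["PET", "CT"] = "PET"

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={data.ndim}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")
        object.__setattr__(self, "spacing", spacing)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class ROIMask:
    """Binary tumour mask on the same grid as its :class:`ImageVolume`.

    Multiple connected components are allowed (primary tumour plus involved
    lymph nodes form a single region of interest).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={data.ndim}")
        data = data.astype(bool)
        object.__setattr__(self, "data", data)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")
        object.__setattr__(self, "spacing", spacing)
        if not data.any():
            raise ValueError("ROI mask is empty (no voxel set)")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class TextureParams:
    """One point of the 5 x 2 x 4 texture-extraction parameter grid."""

    voxel_size_mm: float
    quant_algo: str
    n_gray: int

    def __post_init__(self):
        if float(self.voxel_size_mm) not in VOXEL_SIZES_MM:
            raise ValueError(f"voxel_size_mm must be one of {VOXEL_SIZES_MM}")
        if self.quant_algo not in QUANT_ALGOS:
            raise ValueError(f"quant_algo must be one of {QUANT_ALGOS}")
        if int(self.n_gray) not in GRAY_LEVELS:
            raise ValueError(f"n_gray must be one of {GRAY_LEVELS}")
        object.__setattr__(self, "voxel_size_mm", float(self.voxel_size_mm))
        object.__setattr__(self, "n_gray", int(self.n_gray))

    @property
    def tag(self) -> str:
        algo = "Equal" if self.quant_algo == "EqualProbability" else "Uniform"
        return f"vx{self.voxel_size_mm:g}mm_{algo}_Ng{self.n_gray}"


def enumerate_texture_grid() -> list[TextureParams]:
    """All 40 combinations of voxel size, quantizer and number of gray levels."""
    return [
        TextureParams(s, a, g)
        for s, a, g in itertools.product(VOXEL_SIZES_MM, QUANT_ALGOS, GRAY_LEVELS)
    ]


@dataclass(frozen=True)
class QuantizedROI:
    """Integer gray levels 1..n_gray inside the ROI, sentinel 0 outside."""

    levels: np.ndarray
    n_gray: int
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        levels = np.ascontiguousarray(self.levels, dtype=np.int64)
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        inside = levels[levels != OUTSIDE]
        if inside.size == 0:
            raise ValueError("quantized ROI is empty")
        if inside.min() < 1 or inside.max() > self.n_gray:
            raise ValueError("gray levels outside 1..n_gray")

    @property
    def mask(self) -> np.ndarray:
        return self.levels != OUTSIDE

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# resampling


def resample_isotropic(
    vol: ImageVolume,
    mask: ROIMask,
    s: float,
    image_order: int = 3,
    mask_order: int = 1,
) -> tuple[ImageVolume, ROIMask]:
    """Resample a volume/mask pair onto an isotropic grid of ``s`` mm voxels.

    The output grid is anchored at the input volume's origin (corner of voxel
    (0,0,0)) and covers the ROI bounding box padded by one output voxel,
    clipped to the input volume extent.  Image values are interpolated with a
    cubic spline (``image_order``); the mask is interpolated linearly and
    re-binarized at 0.5.  If the input already has spacing ``(s, s, s)`` the
    inputs are returned unchanged.
    """
    if vol.data.shape != mask.data.shape:
        raise ValueError("volume and mask shapes differ")
    if vol.spacing != mask.spacing:
        raise ValueError("volume and mask spacings differ")
    s = float(s)
    if s <= 0:
        raise ValueError("target voxel size must be positive")
    if vol.spacing == (s, s, s):
        return vol, mask

    spacing = np.asarray(vol.spacing)
    shape = np.asarray(vol.data.shape)
    extent = spacing * shape  # world-space size, origin at 0

    idx = np.argwhere(mask.data)
    # ROI bounding box in world coordinates (voxel outer edges)
    lo_w = idx.min(axis=0) * spacing
    hi_w = (idx.max(axis=0) + 1) * spacing
    # pad by one output voxel, clip to the volume extent, snap to the s-grid
    lo_w = np.maximum(lo_w - s, 0.0)
    hi_w = np.minimum(hi_w + s, extent)
    start = np.floor(lo_w / s + 1e-9).astype(int)
    stop = np.ceil(hi_w / s - 1e-9).astype(int)
    out_shape = np.maximum(stop - start, 1)

    # output voxel centers in world coordinates -> input index coordinates
    grids = [
        (start[a] + np.arange(out_shape[a]) + 0.5) * s / spacing[a] - 0.5
        for a in range(3)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    coords = np.stack([c.ravel() for c in coords])

    img = ndimage.map_coordinates(
        vol.data, coords, order=image_order, mode="nearest"
    ).reshape(tuple(out_shape))
    msk = ndimage.map_coordinates(
        mask.data.astype(float), coords, order=mask_order, mode="constant", cval=0.0
    ).reshape(tuple(out_shape))
    msk = msk >= 0.5
    if not msk.any():
        raise ValueError(f"ROI empty after resampling to {s:g} mm isotropic voxels")

    new_spacing = (s, s, s)
    return (
        ImageVolume(img, new_spacing, vol.modality),
        ROIMask(msk, new_spacing),
    )


# ---------------------------------------------------------------------------
# quantization


def quantize_uniform(vol: ImageVolume, mask: ROIMask, n_gray: int) -> QuantizedROI:
    """Uniform-width quantization of ROI intensities into ``n_gray`` levels.

    Bin width is (max - min)/n_gray over ROI voxels only;
    level = min(n_gray, floor(n_gray * (x - min)/(max - min)) + 1), so the ROI
    minimum maps to 1 and the maximum to n_gray.  A constant ROI maps entirely
    to level 1 (degenerate rule).
    """
    n_gray = int(n_gray)
    if n_gray < 2:
        raise ValueError("n_gray must be >= 2")
    m = mask.data
    vals = vol.data[m]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(vol.data.shape, dtype=np.int64)
    if hi == lo:
        levels[m] = 1
    else:
        lv = np.floor(n_gray * (vals - lo) / (hi - lo)).astype(np.int64) + 1
        np.minimum(lv, n_gray, out=lv)
        levels[m] = lv
    return QuantizedROI(levels, n_gray, vol.spacing)


def quantize_equalprob(vol: ImageVolume, mask: ROIMask, n_gray: int) -> QuantizedROI:
    """Equal-probability (histogram equalization) quantization.

    Levels are assigned from the lower empirical CDF:
    level(x) = floor(n_gray * P(X < x)) + 1, which for all-distinct values
    yields per-level counts differing by at most one, and under heavy ties
    keeps each tied group in a single level (some levels may stay empty).
    """
    n_gray = int(n_gray)
    if n_gray < 2:
        raise ValueError("n_gray must be >= 2")
    m = mask.data
    vals = vol.data[m]
    n = vals.size
    order = np.argsort(vals, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    # lower CDF: number of strictly smaller values (ties share their group's min rank)
    sorted_vals = vals[order]
    first_of_group = np.concatenate(([0], np.nonzero(np.diff(sorted_vals))[0] + 1))
    group_id = np.cumsum(np.concatenate(([0], (np.diff(sorted_vals) != 0).astype(np.int64))))
    below = first_of_group[group_id]  # per sorted position
    below_per_point = np.empty(n, dtype=np.int64)
    below_per_point[order] = below
    lv = (n_gray * below_per_point) // n + 1
    levels = np.zeros(vol.data.shape, dtype=np.int64)
    levels[m] = lv
    return QuantizedROI(levels, n_gray, vol.spacing)


def quantize(vol: ImageVolume, mask: ROIMask, params: TextureParams) -> QuantizedROI:
    fn = quantize_equalprob if params.quant_algo == "EqualProbability" else quantize_uniform
    return fn(vol, mask, params.n_gray)


# ---------------------------------------------------------------------------
# NIfTI I/O (nibabel)


def load_nifti_pair(volume_path, mask_path, modality: str = "PET") -> tuple[ImageVolume, ROIMask]:
    """Read a volume and its aligned binary mask from NIfTI files.

    Both files must share shape and affine; spacing is taken from the header.
    """
    import nibabel as nib

    iv = nib.load(str(volume_path))
    im = nib.load(str(mask_path))
    if iv.shape != im.shape:
        raise ValueError(f"shape mismatch: volume {iv.shape} vs mask {im.shape}")
    if not np.allclose(iv.affine, im.affine, atol=1e-4):
        raise ValueError("volume and mask affines differ")
    spacing = tuple(float(z) for z in iv.header.get_zooms()[:3])
    vol = ImageVolume(np.asarray(iv.dataobj, dtype=float), spacing, modality)
    mask = ROIMask(np.asarray(im.dataobj) > 0.5, spacing)
    return vol, mask


def save_nifti(path, data: np.ndarray, spacing: Sequence[float]) -> None:
    import nibabel as nib

    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
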