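"""Volume/mask I/O, tumor volumetry and gray-level discretization.

Volumes are contrast-enhanced T1 MRI grids; masks are binary tumor ROIs on
the same grid.  Only voxel spacing is consumed from the NIfTI affine; all
indexing is 0-based voxel space.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeImage",
    "ROIMask",
    "GrayLevelImage",
    "GridMismatchError",
    "MaskError",
    "read_volume_and_mask",
    "write_volume",
    "compute_volume_cm3",
    "resection_rate",
    "discretize_fixed_bins",
    "discretize_fixed_width",
]

DEFAULT_N_BINS = 32


class GridMismatchError(ValueError):
    """Volume and mask do not share a voxel grid."""


class MaskError(ValueError):
    """Mask contains values outside {0, 1}."""


@dataclass(frozen=True)
class VolumeImage:
    """3D scalar intensity grid with per-axis voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume contains non-finite intensities")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class ROIMask:
    """Binary tumor region on the grid of its paired :class:`VolumeImage`."""

    data: np.ndarray

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {data.shape}")
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise MaskError(f"mask values must be in {{0,1}}, found {uniq}")
        object.__setattr__(self, "data", data.astype(bool))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class GrayLevelImage:
    """Discretized intensities: integer levels 1..n_levels in-mask, 0 outside."""

    data: np.ndarray
    n_levels: int

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.int64)
        if data.ndim != 3:
            raise ValueError("gray-level image must be 3D")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        inside = data > 0
        if inside.any() and data[inside].max() > self.n_levels:
            raise ValueError("gray level exceeds n_levels")
        object.__setattr__(self, "data", data)


def read_volume_and_mask(volume_path, mask_path) -> tuple[VolumeImage, ROIMask]:
    """Load a NIfTI volume and its binary ROI mask as a checked pair.

    Spacing is taken from the volume header.  The pair must agree in shape
    and affine (to 1e-4); the mask must be strictly {0,1}.
    """
    vol_img = nib.load(str(volume_path))
    mask_img = nib.load(str(mask_path))
    vol_data = np.asarray(vol_img.get_fdata(), dtype=float)
    mask_data = np.asarray(mask_img.get_fdata())
    if vol_data.shape != mask_data.shape:
        raise GridMismatchError(
            f"volume shape {vol_data.shape} != mask shape {mask_data.shape}"
        )
    if not np.allclose(vol_img.affine, mask_img.affine, atol=1e-4):
        raise GridMismatchError("volume and mask affines differ")
    if not np.all(np.isin(np.unique(mask_data), (0.0, 1.0))):
        raise MaskError("mask is not binary {0,1}")
    spacing = tuple(float(z) for z in vol_img.header.get_zooms()[:3])
    return VolumeImage(vol_data, spacing), ROIMask(mask_data.astype(np.int8))


def write_volume(path, data: np.ndarray, spacing) -> None:
    """Write a 3D array as NIfTI with a diagonal affine from *spacing* (mm)."""
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def compute_volume_cm3(mask: ROIMask, spacing) -> float:
    """Tumor volume in cm^3 = voxel count x voxel volume (mm^3) / 1000."""
    sx, sy, sz = (float(s) for s in spacing)
    if min(sx, sy, sz) <= 0:
        raise ValueError("spacing components must be positive")
    return mask.n_voxels * sx * sy * sz / 1000.0


def resection_rate(v_pre: float, v_res: float) -> float:
    """Fraction of the preoperative tumor removed, clamped to [0, 1].

    rate = (v_pre - v_res) / v_pre.  Clamping absorbs segmentation noise
    where the postoperative residual slightly exceeds the preoperative
    volume.
    """
    if v_pre <= 0:
        raise ValueError(f"preoperative volume must be > 0, got {v_pre}")
    if v_res < 0:
        raise ValueError(f"residual volume must be >= 0, got {v_res}")
    return float(np.clip((v_pre - v_res) / v_pre, 0.0, 1.0))


def discretize_fixed_bins(
    volume: VolumeImage, mask: ROIMask, n_bins: int = DEFAULT_N_BINS
) -> GrayLevelImage:
    """Bin masked intensities into *n_bins* equal-width gray levels.

    Bins cover [min, max] of the in-mask intensities; the top edge is
    inclusive.  A constant ROI (zero range) maps every masked voxel to
    level 1.  Voxels outside the mask get level 0.
    """
    if volume.shape != mask.shape:
        raise GridMismatchError("volume/mask shape mismatch")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    m = mask.data
    if not m.any():
        raise ValueError("empty mask")
    vals = volume.data[m]
    lo, hi = float(vals.min()), float(vals.max())
    out = np.zeros(volume.shape, dtype=np.int64)
    if hi == lo:
        out[m] = 1
    else:
        width = (hi - lo) / n_bins
        levels = np.floor((vals - lo) / width).astype(np.int64) + 1
        np.clip(levels, 1, n_bins, out=levels)  # top edge inclusive
        out[m] = levels
    return GrayLevelImage(out, n_bins)


def discretize_fixed_width(
    volume: VolumeImage, mask: ROIMask, bin_width: float
) -> GrayLevelImage:
    """Bin masked intensities into gray levels of fixed width *bin_width*.

    Levels are anchored at the in-mask minimum, so the number of levels
    adapts to the ROI's dynamic range.  Unlike a fixed bin count, the
    resolution of the discretization does not shrink when the intensity
    range widens, which keeps texture features comparable across patients;
    choose a width comparable to the image noise SD.
    """
    if volume.shape != mask.shape:
        raise GridMismatchError("volume/mask shape mismatch")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    m = mask.data
    if not m.any():
        raise ValueError("empty mask")
    vals = volume.data[m]
    levels = np.floor((vals - vals.min()) / bin_width).astype(np.int64) + 1
    out = np.zeros(volume.shape, dtype=np.int64)
    out[m] = levels
    return GrayLevelImage(out, int(levels.max()))
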