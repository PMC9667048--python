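"""Volume containers, Gaussian smoothing and global-uptake scaling.

The preprocessing chain applied to every scan before feature extraction is

1. restrict all statistics to a binary brain mask,
2. smooth with an isotropic 3-D Gaussian kernel specified by its full width
   at half maximum (FWHM, default 10 mm),
3. divide by the whole-brain (masked) mean so every scan has unit global
   uptake.

Smoothing uses a mask-renormalized convolution: the Gaussian weights of
out-of-mask voxels are redistributed onto in-mask voxels, which keeps the
masked mean essentially unchanged and avoids the downward bias that plain
zero-padded convolution would impose on parcels near the brain edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

#: FWHM / sigma ratio of a Gaussian, 2 * sqrt(2 * ln 2).
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Convert a Gaussian full width at half maximum to its sigma (mm)."""
    if fwhm_mm <= 0:
        raise ValueError(f"FWHM must be positive, got {fwhm_mm!r}")
    return fwhm_mm / FWHM_PER_SIGMA


@dataclass
class Volume:
    """A 3-D uptake grid with voxel spacing and a binary brain mask.

    Parameters
    ----------
    data
        Non-negative intensity grid (arbitrary uptake units).
    spacing_mm
        Physical voxel size along each axis, all positive.
    mask
        Boolean grid of the same shape; all statistics are computed over
        in-mask voxels only and background is never imputed.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if self.data.shape != self.mask.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != data shape {self.data.shape}"
            )
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def masked_values(self) -> np.ndarray:
        """Intensities of in-mask voxels in C (row-major) scan order."""
        return self.data[self.mask]

    def masked_mean(self) -> float:
        return float(self.data[self.mask].mean())

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(data=data, spacing_mm=self.spacing_mm, mask=self.mask)


@dataclass
class Atlas:
    """A labeled parcellation on a voxel grid.

    ``labels`` uses 0 for background; every positive id present in
    ``label_table`` (except composite ids) labels a non-empty parcel.
    Composite ROIs — unions of base parcels added by
    :func:`petdx.roifeat.merge_rois` — live in ``composites`` and never
    appear in the label grid themselves.
    """

    labels: np.ndarray
    label_table: dict[int, str]
    spacing_mm: tuple[float, float, float]
    composites: dict[int, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integer")
        if 0 in self.label_table:
            raise ValueError("background id 0 must not appear in the label table")
        present = set(np.unique(self.labels)) - {0}
        for lab in self.label_table:
            if lab in self.composites:
                continue
            if lab not in present:
                raise ValueError(f"label {lab} in table but absent from grid")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def mask(self) -> np.ndarray:
        """Brain mask implied by the parcellation (any labeled voxel)."""
        return self.labels > 0

    @property
    def roi_ids(self) -> list[int]:
        """ROI ids in label-table insertion order (base, then composites)."""
        return list(self.label_table)

    def base_ids(self) -> list[int]:
        return [i for i in self.label_table if i not in self.composites]

    def parcel_mask(self, roi_id: int) -> np.ndarray:
        """Boolean voxel mask of one ROI (composites = union of members)."""
        if roi_id in self.composites:
            out = np.zeros_like(self.labels, dtype=bool)
            for member in self.composites[roi_id]:
                out |= self.labels == member
            return out
        return self.labels == roi_id


def smooth(volume: Volume, fwhm_mm: float) -> Volume:
    """Smooth within the mask with an isotropic Gaussian of given FWHM.

    The per-axis sigma in voxels is ``fwhm_to_sigma(fwhm_mm) / spacing``,
    so anisotropic voxel grids are handled per axis.  ``fwhm_mm = 0``
    returns the input unchanged.  Outside the mask the output is zero.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be >= 0")
    if fwhm_mm == 0:
        return volume
    sigma_vox = [fwhm_to_sigma(fwhm_mm) / s for s in volume.spacing_mm]
    mask_f = volume.mask.astype(float)
    num = ndimage.gaussian_filter(
        np.where(volume.mask, volume.data, 0.0), sigma_vox, mode="constant", cval=0.0
    )
    den = ndimage.gaussian_filter(mask_f, sigma_vox, mode="constant", cval=0.0)
    out = np.zeros_like(num)
    inside = volume.mask
    out[inside] = num[inside] / den[inside]
    return volume.with_data(out)


def global_scale(volume: Volume) -> tuple[Volume, float]:
    """Divide a volume by its masked mean (global-uptake normalization).

    Returns the scaled volume (masked mean exactly 1 up to floating
    tolerance) together with the global mean that was removed.  Scans
    differing only by a positive factor map to the same output, which makes
    downstream ROI uptake ratios scale-free.
    """
    mean = volume.masked_mean()
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError(f"masked mean must be positive, got {mean!r}")
    return volume.with_data(volume.data / mean), mean
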