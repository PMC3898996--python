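"""Image-domain utilities: tissue totals, smoothing, masking, NIfTI I/O.

The central container is :class:`GMVolumeSet`, a stack of modulated
gray-matter maps for all subjects on a shared voxel grid, stored as a
``subjects x voxels`` array.  Voxel values are modulated GM density
(unitless); voxel sizes are millimetres; volumes are reported in
millilitres (1 mL = 1000 mm^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "GMVolumeSet",
    "BrainMask",
    "compute_tissue_totals",
    "compute_tiv",
    "gaussian_smooth",
    "mean_image",
    "make_mask",
    "fwhm_to_sigma",
]

MM3_PER_ML = 1000.0


def _default_affine(voxel_size: float) -> np.ndarray:
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    return aff


@dataclass
class GMVolumeSet:
    """Per-subject modulated GM images on a common grid.

    ``data`` is ``(n_subjects, n_voxels)`` with voxels in C (row-major)
    order of ``shape``.  Subject order is the single source of truth for
    row alignment with the cohort table.
    """

    data: np.ndarray
    shape: tuple[int, int, int]
    voxel_size: float
    subject_ids: list[str] = field(default_factory=list)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_subjects, n_voxels)")
        if self.data.shape[1] != int(np.prod(self.shape)):
            raise ValueError(
                f"data has {self.data.shape[1]} voxels but shape {self.shape} "
                f"implies {int(np.prod(self.shape))}"
            )
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)
        if not self.subject_ids:
            self.subject_ids = [f"S{i:04d}" for i in range(len(self.data))]

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size**3 / MM3_PER_ML

    def as_volume(self, i: int) -> np.ndarray:
        """Subject ``i`` as a 3-D array."""
        return self.data[i].reshape(self.shape)

    def copy_with(self, data: np.ndarray) -> "GMVolumeSet":
        return GMVolumeSet(
            data=data,
            shape=self.shape,
            voxel_size=self.voxel_size,
            subject_ids=list(self.subject_ids),
            affine=None if self.affine is None else self.affine.copy(),
        )

    def to_nifti(self) -> nib.Nifti1Image:
        """4-D NIfTI (x, y, z, subject)."""
        vol = self.data.reshape((self.n_subjects, *self.shape))
        return nib.Nifti1Image(np.moveaxis(vol, 0, -1), self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(
        cls,
        path: str | Path,
        subject_ids: Sequence[str] | None = None,
    ) -> "GMVolumeSet":
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=np.float64)
        if arr.ndim == 3:
            arr = arr[..., None]
        data = np.moveaxis(arr, -1, 0).reshape(arr.shape[-1], -1)
        voxel_size = float(np.abs(img.affine[0, 0]))
        return cls(
            data=data,
            shape=arr.shape[:3],
            voxel_size=voxel_size,
            subject_ids=list(subject_ids or []),
            affine=np.asarray(img.affine),
        )


@dataclass
class BrainMask:
    """Binary analysis mask on the same grid as the image set."""

    mask: np.ndarray  # flat boolean, n_voxels
    shape: tuple[int, int, int]
    voxel_size: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool).ravel()
        if self.mask.size != int(np.prod(self.shape)):
            raise ValueError("mask size does not match grid shape")
        if not self.mask.any():
            raise ValueError(
                "mask is empty; consider lowering the mean-image threshold"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(
            self.mask.reshape(self.shape).astype(np.uint8),
            _default_affine(self.voxel_size),
        )

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))


def compute_tissue_totals(
    images: GMVolumeSet | np.ndarray, voxel_size: float | None = None
) -> np.ndarray:
    """Total tissue volume per subject, in mL.

    Integrates each (nonnegative) tissue map over all voxels and
    multiplies by the voxel volume.
    """
    if isinstance(images, GMVolumeSet):
        data = images.data
        voxel_size = images.voxel_size
    else:
        data = np.atleast_2d(np.asarray(images, dtype=np.float64))
        if voxel_size is None:
            raise ValueError("voxel_size is required for a bare array")
    if np.any(data < 0):
        raise ValueError("tissue maps must be nonnegative")
    return data.sum(axis=1) * (voxel_size**3 / MM3_PER_ML)


def compute_tiv(tgm, twm, tcsf) -> np.ndarray:
    """Total intracranial volume: TGM + TWM + TCSF (mL)."""
    parts = []
    for name, v in (("tgm", tgm), ("twm", twm), ("tcsf", tcsf)):
        if v is None:
            raise ValueError(f"missing tissue class volume: {name}")
        arr = np.asarray(v, dtype=np.float64)
        if np.any(np.isnan(arr)):
            raise ValueError(f"NaN in tissue class volume: {name}")
        if np.any(arr < 0):
            raise ValueError(f"negative tissue class volume: {name}")
        parts.append(arr)
    return parts[0] + parts[1] + parts[2]


def fwhm_to_sigma(fwhm_mm: float, voxel_size: float) -> float:
    """Gaussian sigma in voxels for a given FWHM in mm."""
    return fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size


def gaussian_smooth(images: GMVolumeSet, fwhm_mm: float) -> GMVolumeSet:
    """Isotropic Gaussian smoothing with mirrored (reflect) boundaries.

    ``fwhm_mm = 0`` is the identity.  Reflect padding approximately
    preserves the total image sum, unlike implicit zero padding.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm_mm == 0:
        return images.copy_with(images.data.copy())
    sigma = fwhm_to_sigma(fwhm_mm, images.voxel_size)
    out = np.empty_like(images.data)
    for i in range(images.n_subjects):
        out[i] = ndimage.gaussian_filter(
            images.as_volume(i), sigma=sigma, mode="reflect"
        ).ravel()
    return images.copy_with(out)


def mean_image(images: GMVolumeSet) -> np.ndarray:
    """Across-subject mean image (flat)."""
    return images.data.mean(axis=0)


def make_mask(smoothed: GMVolumeSet, threshold: float = 0.1) -> BrainMask:
    """Binary mask: across-subject mean of the smoothed images > threshold.

    The same mask is meant to be applied to every statistical model so
    the adjustment modes remain directly comparable.
    """
    if smoothed.n_subjects == 0:
        raise ValueError("empty image set")
    m = mean_image(smoothed) > threshold
    if not m.any():
        raise ValueError(
            f"mask is empty at threshold {threshold}; lower the threshold"
        )
    return BrainMask(mask=m, shape=smoothed.shape, voxel_size=smoothed.voxel_size)
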