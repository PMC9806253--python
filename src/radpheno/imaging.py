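"""Volumetric image handling for DCE-MRI radiomics.

The unit of computation is a :class:`VolumeWithMask`: one 3D intensity
array (arbitrary MRI units), its voxel spacing in mm, and a binary
whole-tumor ROI of the same shape.  This module covers the image-side
plumbing of the pipeline: NIfTI I/O, post-minus-pre subtraction images,
isotropic resampling, extraction of the inner peripheral rim of the
tumor (distances measured in physical mm), and fixed-bin-count gray
level discretization feeding the texture matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class VolumeWithMask:
    """A 3D intensity volume with voxel spacing and a binary ROI mask.

    Parameters
    ----------
    intensities : ndarray, shape (nx, ny, nz)
        Image intensities in arbitrary units.
    spacing : tuple of float
        Voxel size ``(dx, dy, dz)`` in mm; all components positive.
    mask : ndarray of bool, same shape
        Region of interest; ``True`` marks tumor voxels.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if self.mask.shape != self.intensities.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match image shape "
                f"{self.intensities.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensities.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def mask_volume_mm3(self) -> float:
        """Physical ROI volume: voxel count times voxel volume."""
        return float(self.mask.sum()) * self.voxel_volume_mm3

    def copy(self) -> "VolumeWithMask":
        return VolumeWithMask(self.intensities.copy(), self.spacing, self.mask.copy())

    def with_mask(self, mask: np.ndarray) -> "VolumeWithMask":
        """Same image, different ROI."""
        return VolumeWithMask(self.intensities, self.spacing, mask)


@dataclass
class DiscretizedVolume:
    """Gray-level quantized volume: integer levels 1..G inside the ROI, 0 outside."""

    levels: np.ndarray
    n_levels: int
    spacing: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        inmask = self.levels[self.levels > 0]
        if inmask.size and inmask.max() > self.n_levels:
            raise ValueError("levels exceed n_levels")

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0


def _spacing_from_nifti(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError("volume is missing usable voxel-spacing metadata")
    return tuple(float(z) for z in zooms)


def read_volume(image_path, mask_path) -> VolumeWithMask:
    """Read an image/mask NIfTI pair into a :class:`VolumeWithMask`.

    The mask file uses integer labels; any value > 0 is foreground.
    Image and mask must share a shape; the image's spacing metadata is
    authoritative.
    """
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    mdata = np.asarray(msk.get_fdata())
    if data.ndim != 3 or mdata.ndim != 3:
        raise ValueError("expected 3D image and mask volumes")
    if data.shape != mdata.shape:
        raise ValueError(
            f"image shape {data.shape} and mask shape {mdata.shape} differ"
        )
    return VolumeWithMask(data, _spacing_from_nifti(img), mdata > 0)


def write_volume(v: VolumeWithMask, image_path, mask_path=None) -> None:
    """Write a volume (and optionally its mask) as NIfTI with spacing in the affine."""
    affine = np.diag(list(v.spacing) + [1.0])
    nib.save(nib.Nifti1Image(v.intensities.astype(np.float32), affine), str(image_path))
    if mask_path is not None:
        nib.save(
            nib.Nifti1Image(v.mask.astype(np.uint8), affine), str(mask_path)
        )


def subtraction_image(post: VolumeWithMask, pre: VolumeWithMask) -> VolumeWithMask:
    """Voxelwise post-contrast minus pre-contrast image.

    Mirrors the contrast-enhancement subtraction used to delineate the
    tumor ROI (second post-contrast phase minus pre-contrast).  The ROI
    mask of ``post`` is carried through unchanged.
    """
    if post.shape != pre.shape:
        raise ValueError("post and pre volumes must share a shape")
    if not np.allclose(post.spacing, pre.spacing):
        raise ValueError("post and pre volumes must share a spacing")
    return VolumeWithMask(post.intensities - pre.intensities, post.spacing, post.mask)


def resample_isotropic(v: VolumeWithMask, target_mm: float = 1.0) -> VolumeWithMask:
    """Resample to isotropic voxels: linear for intensities, nearest for the mask.

    A no-op (voxel-identical copy) when the input is already at the
    target spacing.
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be > 0")
    if np.allclose(v.spacing, target_mm):
        return v.copy()
    factors = np.asarray(v.spacing) / target_mm
    intens = ndimage.zoom(v.intensities, factors, order=1, mode="nearest")
    mask = ndimage.zoom(v.mask.astype(np.uint8), factors, order=0, mode="nearest") > 0
    out = VolumeWithMask(intens, (target_mm,) * 3, mask)
    # A mask whose physical extent exceeds target_mm on every axis cannot
    # legitimately vanish under nearest-neighbour resampling.
    if v.mask.any() and not mask.any():
        extents = [
            (np.ptp(idx) + 1) * s
            for idx, s in zip(np.nonzero(v.mask), v.spacing)
        ]
        if all(e >= target_mm for e in extents):
            raise RuntimeError(
                "resampling emptied a mask larger than the target spacing "
                "(interpolation bug)"
            )
    return out


def peripheral_rim(v: VolumeWithMask, rim_mm: float = 2.0) -> VolumeWithMask:
    """Restrict the ROI to the inner rim of the tumor.

    The rim is the set of in-mask voxels whose Euclidean distance (in mm,
    using the voxel spacing) to the nearest out-of-mask voxel is at most
    ``rim_mm``.  The tumor periphery of the analysis is the inner 2-mm rim
    of the whole-tumor ROI, hence the default.  The rim is always a subset
    of the whole mask and is non-empty whenever the whole mask is.
    """
    if rim_mm <= 0:
        raise ValueError("rim_mm must be > 0")
    if not v.mask.any():
        raise ValueError("cannot take the rim of an empty mask")
    dist = ndimage.distance_transform_edt(v.mask, sampling=v.spacing)
    rim = v.mask & (dist <= rim_mm)
    return v.with_mask(rim)


def discretize(v: VolumeWithMask, n_levels: int = 32) -> DiscretizedVolume:
    """Fixed-bin-count gray-level quantization over the in-mask intensity range.

    ``level = min(G, floor(G * (x - min) / (max - min)) + 1)``; a constant
    region maps entirely to level 1.  Fixed bin *count* (rather than fixed
    bin width) keeps matrix sizes bounded and makes all downstream texture
    features invariant to affine intensity rescaling — the appropriate
    convention for arbitrary-unit MRI.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if not v.mask.any():
        raise ValueError("cannot discretize an empty mask")
    levels = np.zeros(v.shape, dtype=np.int64)
    vals = v.intensities[v.mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        levels[v.mask] = 1
    else:
        q = np.floor(n_levels * (vals - lo) / (hi - lo)).astype(np.int64) + 1
        levels[v.mask] = np.minimum(q, n_levels)
    return DiscretizedVolume(levels, n_levels, v.spacing)


def crop_to_mask(v: VolumeWithMask, margin: int = 1, *extra_masks: np.ndarray):
    """Crop a volume to the bounding box of its mask plus ``margin`` voxels.

    Texture matrices only see in-mask voxels and their immediate
    neighbourhood, so a tight crop is exact for feature extraction and much
    faster.  When wavelet filtering follows, use a margin at least as large
    as the filter support so in-mask reconstructions are unaffected by the
    crop.  Any ``extra_masks`` (e.g. the rim ROI) are cropped to the same box.
    """
    if not v.mask.any():
        raise ValueError("cannot crop to an empty mask")
    sl = []
    for idx, n in zip(np.nonzero(v.mask), v.shape):
        lo = max(int(idx.min()) - margin, 0)
        hi = min(int(idx.max()) + margin + 1, n)
        sl.append(slice(lo, hi))
    sl = tuple(sl)
    out = VolumeWithMask(v.intensities[sl], v.spacing, v.mask[sl])
    if extra_masks:
        return out, tuple(m[sl] for m in extra_masks)
    return out
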