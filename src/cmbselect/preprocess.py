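"""Volume I/O, canonical reorientation, brain masking and intensity standardization.

Images are held as :class:`VolumeImage`: a 3-D scalar voxel grid plus a
NIfTI-style affine from which physical voxel dimensions and anatomical axis
labels are derived.  No resampling or registration is ever performed — the
pipeline operates in native space because microbleeds are only a few voxels
across and interpolation would degrade them.  Reorientation is restricted to
axis permutations and flips, which relabel axes without touching any voxel
intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu


class VolumeFormatError(ValueError):
    """Raised when a file cannot be interpreted as a single 3-D volume."""


@dataclass
class VolumeImage:
    """A 3-D scalar image in native space.

    Parameters
    ----------
    voxels:
        3-D array of intensities.
    affine:
        4x4 voxel-to-world affine (NIfTI convention, mm units).
    """

    voxels: np.ndarray
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3-D volume, got {self.voxels.ndim}-D data"
            )
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise VolumeFormatError("affine must be 4x4")
        if np.any(np.asarray(self.voxel_size_mm) <= 0):
            raise VolumeFormatError("voxel sizes must be strictly positive")

    @classmethod
    def from_voxel_size(cls, voxels: np.ndarray, voxel_size_mm) -> "VolumeImage":
        """Build an axis-aligned volume from voxel data and spacings."""
        aff = np.diag(list(voxel_size_mm) + [1.0])
        return cls(np.asarray(voxels), aff)

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        sizes = np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))
        return tuple(float(s) for s in sizes)

    @property
    def axis_labels(self) -> tuple[str, str, str]:
        """Anatomical codes of the three array axes (e.g. ('R', 'A', 'S'))."""
        return tuple(nib.aff2axcodes(self.affine))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def with_voxels(self, voxels: np.ndarray) -> "VolumeImage":
        """Same geometry, new data."""
        return VolumeImage(np.asarray(voxels), self.affine.copy())


def read_volume(path) -> VolumeImage:
    """Read a NIfTI-1/2 file as a :class:`VolumeImage`.

    The voxel grid and affine are taken from the header unchanged; no
    resampling is applied.  Non-3-D files are rejected.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise VolumeFormatError(f"cannot read {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path}: expected a 3-D volume, got shape {data.shape}"
        )
    return VolumeImage(np.asarray(data, dtype=np.float64), img.affine)


def write_volume(vol: VolumeImage, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float32), vol.affine), str(path))


def write_mask(mask: np.ndarray, like: VolumeImage, path) -> None:
    """Write a binary or integer label mask on the geometry of ``like``."""
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.int16), like.affine), str(path))


def reorient_canonical(vol: VolumeImage) -> VolumeImage:
    """Reorient to canonical (RAS) axis labels by permutation/flips only.

    The multiset of voxel intensities is unchanged; voxel dimensions are
    permuted consistently.  Oblique affines (rotation beyond tolerance)
    trigger a warning and the nearest axis permutation is applied.
    """
    rot = vol.affine[:3, :3]
    # each world axis should be dominated by a single array axis
    with np.errstate(invalid="ignore"):
        dominance = np.abs(rot) / np.maximum(
            np.sqrt((rot**2).sum(axis=0, keepdims=True)), 1e-12
        )
    if dominance.max(axis=0).min() < 1.0 - 1e-6:
        warnings.warn(
            "oblique affine: applying nearest axis permutation only",
            stacklevel=2,
        )
    img = nib.Nifti1Image(np.asarray(vol.voxels), vol.affine)
    can = nib.as_closest_canonical(img)
    return VolumeImage(np.asanyarray(can.dataobj).astype(vol.voxels.dtype), can.affine)


def compute_brain_mask(vol: VolumeImage, supplied: np.ndarray | None = None) -> np.ndarray:
    """Binary brain mask for ``vol``.

    A supplied mask (e.g. from a dedicated brain-extraction tool) is used
    verbatim after binarization.  The fallback — adequate for phantoms and
    QC, not a skull-stripping replacement — is Otsu thresholding, the
    largest 3-D connected component, morphological closing and hole filling.
    """
    if supplied is not None:
        supplied = np.asarray(supplied)
        if supplied.shape != vol.shape:
            raise ValueError("supplied mask shape does not match image")
        mask = supplied > 0
        if not mask.any():
            raise ValueError("supplied brain mask is empty")
        return mask
    data = vol.voxels
    if np.ptp(data) == 0:
        raise ValueError("cannot compute brain mask of a constant image")
    thr = threshold_otsu(data)
    fg = data > thr
    if not fg.any():
        raise ValueError("brain-mask fallback produced an empty mask")
    labels, n = ndi.label(fg)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        fg = labels == counts.argmax()
    fg = ndi.binary_closing(fg, structure=np.ones((3, 3, 3)), iterations=2)
    fg = ndi.binary_fill_holes(fg)
    if not fg.any():
        raise ValueError("brain-mask fallback produced an empty mask")
    return fg


def standardize_intensity(vol: VolumeImage, mask: np.ndarray) -> VolumeImage:
    """Zero-mean / unit-sd standardization within the brain mask.

    Uses the population standard deviation over mask voxels; voxels outside
    the mask are set to 0.  A constant image inside the mask is an error.
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("brain mask is empty")
    inside = vol.voxels[mask].astype(np.float64)
    mu = inside.mean()
    sd = inside.std()  # population sd
    if sd == 0:
        raise ValueError("zero intensity standard deviation within the brain mask")
    out = np.zeros_like(vol.voxels, dtype=np.float64)
    out[mask] = (vol.voxels[mask] - mu) / sd
    return vol.with_voxels(out)
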