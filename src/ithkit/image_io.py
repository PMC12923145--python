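"""Reading/writing CT volumes and segmentation masks.

Array convention: the first axis is the axial (slice) axis, i.e. arrays are
indexed ``(slice, row, column)`` and ``spacing`` is given in the same order,
in millimetres.  NIfTI files, whose on-disk order is ``(x, y, z)``, are
transposed on read so that the slice axis comes first.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from ithkit import _nrrd
from ithkit.errors import AlignmentError, DegenerateInputError

AXIS_ORDER = ("slice", "row", "column")

_SPACING_RTOL = 1e-3


@dataclass(frozen=True)
class NoduleImage:
    """A CT intensity volume with a co-registered binary nodule mask."""

    intensities: np.ndarray  # 3D, Hounsfield units
    mask: np.ndarray  # 3D, values {0, 1}
    spacing: tuple = (1.0, 1.0, 1.0)  # mm per element, (slice, row, col)
    axis_order: tuple = AXIS_ORDER

    def __post_init__(self):
        ints = np.asarray(self.intensities)
        mask = np.asarray(self.mask)
        if ints.ndim != 3 or mask.ndim != 3:
            raise AlignmentError(
                f"expected 3D grids, got image ndim={ints.ndim}, mask ndim={mask.ndim}"
            )
        if ints.shape != mask.shape:
            raise AlignmentError(
                f"image shape {ints.shape} != mask shape {mask.shape}"
            )
        vals = np.unique(mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise AlignmentError(f"mask must be binary {{0,1}}, found values {vals[:8]}")
        if not mask.any():
            raise DegenerateInputError("mask has no foreground elements")

    @property
    def foreground_count(self) -> int:
        return int(np.asarray(self.mask).sum())


@dataclass(frozen=True)
class PlanarSection:
    """The largest axial cross-section of a nodule (image + mask + origin)."""

    intensities: np.ndarray  # 2D
    mask: np.ndarray  # 2D, {0,1}
    slice_index: int = 0
    spacing: tuple = (1.0, 1.0)  # mm per element, (row, col)

    def __post_init__(self):
        if np.asarray(self.intensities).shape != np.asarray(self.mask).shape:
            raise AlignmentError("section image/mask shapes differ")
        if not np.asarray(self.mask).any():
            raise DegenerateInputError("section mask is empty")


def _read_grid(path):
    """Return ``(array, spacing)`` in (slice,row,col) order from NIfTI or NRRD."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.endswith((".nii", ".nii.gz")):
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        if data.ndim != 3:
            raise DegenerateInputError(f"{path}: expected a 3D image, got ndim={data.ndim}")
        zooms = img.header.get_zooms()[:3]
        # NIfTI order is (x, y, z); slice axis goes first.
        return np.transpose(data, (2, 1, 0)), tuple(float(z) for z in zooms[::-1])
    if path.endswith(".nrrd"):
        data, spacing = _nrrd.read_nrrd(path)
        if data.ndim != 3:
            raise DegenerateInputError(f"{path}: expected a 3D image, got ndim={data.ndim}")
        return data, spacing
    raise ValueError(f"{path}: unsupported image format (use .nii/.nii.gz/.nrrd)")


def _write_grid(path, array, spacing):
    path = os.fspath(path)
    if path.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(spacing[::-1]) + [1.0])
        nib.save(nib.Nifti1Image(np.transpose(array, (2, 1, 0)), affine), path)
    elif path.endswith(".nrrd"):
        _nrrd.write_nrrd(path, array, spacing)
    else:
        raise ValueError(f"{path}: unsupported image format (use .nii/.nii.gz/.nrrd)")


def read_nodule(image_path, mask_path, strict_labels: bool = False) -> NoduleImage:
    """Read an image/mask pair and validate their alignment.

    The mask is binarized by a nonzero test.  With ``strict_labels=True`` a
    mask containing more than one distinct nonzero value is rejected instead.
    """
    intensities, img_spacing = _read_grid(image_path)
    mask_raw, mask_spacing = _read_grid(mask_path)
    if intensities.shape != mask_raw.shape:
        raise AlignmentError(
            f"image {image_path} shape {intensities.shape} != mask {mask_path} "
            f"shape {mask_raw.shape}"
        )
    if not np.allclose(img_spacing, mask_spacing, rtol=_SPACING_RTOL, atol=1e-6):
        raise AlignmentError(
            f"image spacing {img_spacing} != mask spacing {mask_spacing}"
        )
    nonzero = np.unique(mask_raw[mask_raw != 0])
    if strict_labels and nonzero.size > 1:
        raise AlignmentError(f"mask has multiple labels {nonzero[:8]} (strict mode)")
    mask = (mask_raw != 0).astype(np.uint8)
    if not mask.any():
        raise DegenerateInputError(f"mask {mask_path} has no foreground elements")
    return NoduleImage(
        intensities=np.asarray(intensities, dtype=np.float64),
        mask=mask,
        spacing=tuple(img_spacing),
    )


def write_nodule(img: NoduleImage, image_path, mask_path) -> None:
    """Write the image/mask pair; format chosen by file extension."""
    _write_grid(image_path, np.asarray(img.intensities, dtype=np.float64), img.spacing)
    _write_grid(mask_path, np.asarray(img.mask, dtype=np.uint8), img.spacing)


def largest_axial_section(img: NoduleImage) -> PlanarSection:
    """Extract the axial slice with the maximal in-mask element count.

    Ties are broken by the lowest slice index, for determinism.  "Largest"
    is the element count, not physical area; with isotropic in-plane
    spacing the two coincide.
    """
    counts = np.asarray(img.mask).reshape(img.mask.shape[0], -1).sum(axis=1)
    idx = int(np.argmax(counts))  # argmax returns the first maximum
    return PlanarSection(
        intensities=np.asarray(img.intensities[idx], dtype=np.float64),
        mask=np.asarray(img.mask[idx], dtype=np.uint8),
        slice_index=idx,
        spacing=tuple(img.spacing[1:]),
    )
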