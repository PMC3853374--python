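"""Reading and writing CT volumes and compartment masks.

The canonical on-disk format is NIfTI-1 (``.nii`` / ``.nii.gz``).  In memory,
grids are held with a fixed ``(x, y, z)`` axis order — x and y in-plane, z the
axial (slice) direction — and physical spacing in **cm per voxel**, the unit
in which compartment volumes (cm^3) and surface areas (cm^2) are reported.
NIfTI headers carry spacing in mm; the conversion happens on load/save so the
rest of the package never sees mm.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = [
    "CTVolume",
    "CompartmentMask",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
]

MM_PER_CM = 10.0


def _validate_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 components, got {len(spacing)}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing components must be strictly positive, got {spacing}")
    return spacing


def _validate_grid(arr: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 3:
        raise ValueError(f"{what} must be a 3D grid, got {arr.ndim} dimensions")
    if min(arr.shape) < 1:
        raise ValueError(f"{what} must have at least one voxel along each axis")
    return arr


@dataclass
class CTVolume:
    """A 3D CT intensity grid with physical voxel spacing.

    Parameters
    ----------
    intensities:
        3D array indexed ``[x, y, z]``; values on a Hounsfield-unit-like scale.
    spacing:
        ``(dx, dy, dz)`` in cm per voxel along x (in-plane), y (in-plane) and
        z (axial).
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.intensities = _validate_grid(self.intensities, "intensities")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_cm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class CompartmentMask:
    """Integer label grid aligned to a :class:`CTVolume`.

    Label 0 is background; labels ``1..K`` are the contrast-filled
    compartments.  After finalization the label set is gap-free.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = _validate_grid(self.labels, "labels")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.array_equal(self.labels, np.round(self.labels)):
                raise ValueError("mask labels must be integers")
            self.labels = self.labels.astype(np.int32)
        if self.labels.min() < 0:
            raise ValueError("mask labels must be non-negative")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def label_ids(self) -> list[int]:
        """Sorted compartment labels present (background excluded)."""
        ids = np.unique(self.labels)
        return [int(k) for k in ids if k != 0]

    @classmethod
    def for_volume(cls, labels: np.ndarray, volume: CTVolume) -> "CompartmentMask":
        """Associate a label grid with its source volume, checking alignment."""
        labels = _validate_grid(labels, "labels")
        if labels.shape != volume.shape:
            raise ValueError(
                f"mask shape {labels.shape} does not match volume shape {volume.shape}"
            )
        return cls(labels=labels, spacing=volume.spacing)


def _raw_header_zooms(path) -> tuple[float, ...]:
    # nibabel silently repairs non-positive pixdims on load; read the header
    # unchecked so corrupt spacing is reported instead of patched over
    from nibabel.openers import ImageOpener

    with ImageOpener(str(path), "rb") as fh:
        hdr = nib.Nifti1Header.from_fileobj(fh, check=False)
    ndim = int(hdr["dim"][0])
    return tuple(float(z) for z in hdr["pixdim"][1 : 1 + min(ndim, 3)])


def _read_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D in {path}")
    zooms = img.header.get_zooms()[:3]
    raw = _raw_header_zooms(path)
    if any(not np.isfinite(z) or z <= 0 for z in raw):
        raise ValueError(f"non-positive voxel spacing {raw} in header of {path}")
    spacing_cm = tuple(float(z) / MM_PER_CM for z in zooms)
    _validate_spacing(spacing_cm)
    return data, spacing_cm


def _affine_from_spacing(spacing_cm) -> np.ndarray:
    aff = np.eye(4)
    for i, s in enumerate(spacing_cm):
        aff[i, i] = s * MM_PER_CM
    return aff


def load_volume(path) -> CTVolume:
    """Load a 3D NIfTI image as a :class:`CTVolume` (header mm -> cm)."""
    data, spacing = _read_nifti(path)
    return CTVolume(intensities=data.astype(np.float32, copy=False), spacing=spacing)


def save_volume(vol: CTVolume, path) -> None:
    """Write a volume as NIfTI-1 with spacing stored in mm in the header."""
    img = nib.Nifti1Image(
        np.asarray(vol.intensities, dtype=np.float32), _affine_from_spacing(vol.spacing)
    )
    img.header.set_zooms([s * MM_PER_CM for s in vol.spacing])
    nib.save(img, str(path))


def load_mask(path, volume: CTVolume | None = None) -> CompartmentMask:
    """Load a labeled mask; if ``volume`` is given, check shape alignment."""
    data, spacing = _read_nifti(path)
    if not np.array_equal(data, np.round(data)):
        raise ValueError(f"mask file {path} contains non-integer labels")
    labels = data.astype(np.int32)
    if volume is not None:
        return CompartmentMask.for_volume(labels, volume)
    return CompartmentMask(labels=labels, spacing=spacing)


def save_mask(mask: CompartmentMask, path) -> None:
    """Write a mask as integer-typed NIfTI-1."""
    img = nib.Nifti1Image(
        np.asarray(mask.labels, dtype=np.int32), _affine_from_spacing(mask.spacing)
    )
    img.header.set_zooms([s * MM_PER_CM for s in mask.spacing])
    nib.save(img, str(path))
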