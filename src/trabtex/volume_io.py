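"""Reading, writing and cropping of 3D gray-level volumes and masks.

Axis convention
---------------
The third array axis (index 2) is the distal-proximal (longitudinal) axis
throughout the package.  TIFF stacks are stored one transverse slice per
page, so a stack of ``k`` pages maps to an array of shape ``(H, W, k)``.
Elevation angles computed elsewhere are measured against this axis.

Masks are stored as 8-bit 0/255 TIFF or uint8 NIfTI; any nonzero voxel is
treated as foreground on read.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile


class VolumeFormatError(ValueError):
    """Raised when a file cannot be interpreted as a supported volume."""


@dataclasses.dataclass
class GrayVolume:
    """A 3D gray-level image with isotropic voxel size.

    Parameters
    ----------
    data
        3D array of intensities (integer or float), axis 2 = distal-proximal.
    voxel_size_um
        Isotropic voxel edge length in micrometres.
    """

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(f"expected a 3D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 3:
            raise VolumeFormatError(
                f"all three dimensions must be >= 3, got shape {self.data.shape}"
            )
        if not float(self.voxel_size_um) > 0:
            raise VolumeFormatError("voxel_size_um must be positive")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise VolumeFormatError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> float:
        return float(self.voxel_size_um) / 1000.0


@dataclasses.dataclass
class BinaryVolume:
    """A 3D boolean mask (True = bone/foreground) with voxel size metadata."""

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise VolumeFormatError(f"expected a 3D mask, got ndim={self.data.ndim}")
        if not float(self.voxel_size_um) > 0:
            raise VolumeFormatError("voxel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> float:
        return float(self.voxel_size_um) / 1000.0


@dataclasses.dataclass
class SectionImage:
    """A 2D section (histology mode) with isotropic pixel size in micrometres."""

    data: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise VolumeFormatError(f"expected a 2D image, got ndim={self.data.ndim}")
        if min(self.data.shape) < 3:
            raise VolumeFormatError("both dimensions must be >= 3")
        if not float(self.pixel_size_um) > 0:
            raise VolumeFormatError("pixel_size_um must be positive")

    @property
    def pixel_size_mm(self) -> float:
        return float(self.pixel_size_um) / 1000.0


_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _numeric_key(name: str):
    """Sort key that orders slice filenames by embedded integers."""
    parts = re.split(r"(\d+)", name)
    return [int(p) if p.isdigit() else p for p in parts]


def _read_tiff_stack(path: Path) -> np.ndarray:
    if path.is_dir():
        files = sorted(
            (f for f in path.iterdir() if f.suffix.lower() in (".tif", ".tiff")),
            key=lambda f: _numeric_key(f.name),
        )
        if not files:
            raise VolumeFormatError(f"no TIFF slices found in directory {path}")
        slices = [tifffile.imread(str(f)) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1 or slices[0].ndim != 2:
            raise VolumeFormatError("slice files must all be 2D images of one shape")
        arr = np.stack(slices, axis=0)
    else:
        try:
            arr = tifffile.imread(str(path))
        except Exception as exc:  # noqa: BLE001 - wrap any reader failure
            raise VolumeFormatError(f"cannot read TIFF {path}: {exc}") from exc
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise VolumeFormatError(f"TIFF {path} is not a 2D/3D image stack")
    # pages are transverse slices -> slice index becomes axis 2
    return np.moveaxis(arr, 0, -1)


def read_volume(path, voxel_size_um: float | None = None) -> GrayVolume:
    """Read a TIFF stack (multipage file or slice directory) or a NIfTI volume.

    For NIfTI files an isotropic header voxel size (interpreted as mm and
    converted to micrometres) overrides ``voxel_size_um`` when present;
    anisotropic headers are rejected.  TIFF carries no trusted voxel size,
    so ``voxel_size_um`` is required.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such file or directory: {path}")
    if _is_nifti(path):
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj)
        if arr.ndim != 3:
            raise VolumeFormatError(f"NIfTI {path} is not 3D (ndim={arr.ndim})")
        zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
        header_set = np.all(zooms > 0) and not np.allclose(zooms, 1.0)
        if header_set:
            if not np.allclose(zooms, zooms[0], rtol=1e-4):
                raise VolumeFormatError(
                    f"anisotropic NIfTI voxels {tuple(zooms)} are not supported"
                )
            voxel_size_um = float(zooms[0]) * 1000.0
        if voxel_size_um is None:
            raise VolumeFormatError("voxel_size_um required (no usable NIfTI header zoom)")
        return GrayVolume(arr, voxel_size_um)
    if voxel_size_um is None:
        raise VolumeFormatError("voxel_size_um is required for TIFF input")
    arr = _read_tiff_stack(path)
    return GrayVolume(arr, voxel_size_um)


def read_mask(path, voxel_size_um: float | None = None) -> BinaryVolume:
    """Read a mask volume; any nonzero voxel is foreground."""
    vol = read_volume(path, voxel_size_um)
    return BinaryVolume(vol.data != 0, vol.voxel_size_um)


def write_volume(vol: GrayVolume | BinaryVolume, path) -> None:
    """Write a volume as multipage TIFF or NIfTI (by file suffix).

    Binary volumes are stored as 0/255 uint8 so that the files open in
    standard image viewers and in vendor μCT software.
    """
    path = Path(path)
    if isinstance(vol, BinaryVolume):
        data = np.where(vol.data, 255, 0).astype(np.uint8)
    else:
        data = vol.data
    if _is_nifti(path):
        vs_mm = vol.voxel_size_um / 1000.0
        affine = np.diag([vs_mm, vs_mm, vs_mm, 1.0])
        img = nib.Nifti1Image(np.asarray(data), affine)
        img.header.set_zooms((vs_mm, vs_mm, vs_mm))
        nib.save(img, str(path))
        return
    try:
        tifffile.imwrite(str(path), np.moveaxis(np.asarray(data), -1, 0))
    except (OSError, PermissionError) as exc:
        raise OSError(f"cannot write volume to {path}: {exc}") from exc


def extract_roi(vol: GrayVolume, mask: BinaryVolume) -> tuple[GrayVolume, BinaryVolume]:
    """Crop a volume and its region-of-interest mask to the mask bounding box.

    Raises ``ValueError`` for an empty mask (a sample with no trabecular
    bone cannot be analyzed).
    """
    if vol.shape != mask.shape:
        raise ValueError(f"shape mismatch: volume {vol.shape} vs mask {mask.shape}")
    if not mask.data.any():
        raise ValueError("mask is empty: no trabecular bone in the region of interest")
    bounds = []
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        hit = mask.data.any(axis=other)
        idx = np.flatnonzero(hit)
        bounds.append(slice(idx[0], idx[-1] + 1))
    sl = tuple(bounds)
    return (
        GrayVolume(vol.data[sl].copy(), vol.voxel_size_um),
        BinaryVolume(mask.data[sl].copy(), mask.voxel_size_um),
    )
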