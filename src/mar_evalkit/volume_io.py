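"""Data model and I/O for CT volumes and binary masks.

Conventions used throughout the package:

* Arrays are ordered ``(z, y, x)`` — slice, row, column.
* Voxel values are Hounsfield units (air ~ -1000, water = 0).
* Coordinates are voxel-center based; ``origin`` is the physical position
  (mm) of the center of voxel ``(0, 0, 0)``.
* Two volumes (or a volume and a mask) are *aligned* iff their shape,
  spacing and origin are identical; every cross-volume operation in the
  pipeline requires alignment and raises :class:`AlignmentError` otherwise.

NIfTI-1 is the canonical on-disk format (lossless for integer HU within the
12-bit CT range ``[-1024, 4095]``); DICOM CT series are read-only.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path
from typing import Tuple

import numpy as np

from .errors import AlignmentError, FormatError, GeometryError, ValidationError

HU_MIN = -1024
HU_MAX = 4095

MASK_LABELS = frozenset(
    {
        "teeth",
        "metal",
        "body",
        "ctv",
        "ptv",
        "corrected_region",
        "spinal_cord",
        "parotid",
    }
)

_GEOM_ATOL = 1e-4  # tolerant of float32 NIfTI affine round-trips


def _check_geometry(spacing, origin) -> Tuple[Tuple[float, float, float], Tuple[float, float, float]]:
    spacing = tuple(float(s) for s in spacing)
    origin = tuple(float(o) for o in origin)
    if len(spacing) != 3 or len(origin) != 3:
        raise ValidationError("spacing and origin must be length-3 (z, y, x)")
    if any(s <= 0 for s in spacing):
        raise ValidationError(f"spacing components must be strictly positive, got {spacing}")
    return spacing, origin


@dataclasses.dataclass
class CTVolume:
    """A 3D grid of HU values with physical geometry.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        HU values; must be finite.
    spacing : (dz, dy, dx) in mm, all strictly positive.
    origin : (z, y, x) in mm, center of voxel (0, 0, 0).
    case_id : free-form identifier carried through the pipeline.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    case_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"volume data must be 3D, got shape {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise ValidationError("volume contains non-finite HU values")
        self.spacing, self.origin = _check_geometry(self.spacing, self.origin)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def copy(self, data: np.ndarray | None = None) -> "CTVolume":
        return CTVolume(
            data=self.data.copy() if data is None else np.asarray(data),
            spacing=self.spacing,
            origin=self.origin,
            case_id=self.case_id,
        )

    def aligned_with(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=_GEOM_ATOL)
            and np.allclose(self.origin, other.origin, atol=_GEOM_ATOL)
        )

    def require_aligned(self, other, what: str = "operand") -> None:
        if not self.aligned_with(other):
            raise AlignmentError(
                f"{what} is not aligned: shape/spacing/origin "
                f"{other.shape}/{other.spacing}/{other.origin} vs "
                f"{self.shape}/{self.spacing}/{self.origin}"
            )


@dataclasses.dataclass
class VoxelMask:
    """A binary mask on the same grid as a companion :class:`CTVolume`."""

    data: np.ndarray
    label: str
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValidationError(f"mask data must be 3D, got shape {arr.shape}")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.isin(vals, (0, 1)).all():
                raise ValidationError(f"mask values must be in {{0, 1}}, found {vals[:10]}")
            arr = arr.astype(bool)
        self.data = arr
        if self.label not in MASK_LABELS:
            raise ValidationError(f"unknown mask label {self.label!r}; expected one of {sorted(MASK_LABELS)}")
        self.spacing, self.origin = _check_geometry(self.spacing, self.origin)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def physical_volume_ml(self) -> float:
        return self.voxel_count() * float(np.prod(self.spacing)) / 1000.0

    aligned_with = CTVolume.aligned_with
    require_aligned = CTVolume.require_aligned

    def copy(self, data: np.ndarray | None = None, label: str | None = None) -> "VoxelMask":
        return VoxelMask(
            data=self.data.copy() if data is None else np.asarray(data),
            label=self.label if label is None else label,
            spacing=self.spacing,
            origin=self.origin,
        )


def clamp_hu(data: np.ndarray) -> np.ndarray:
    """Clamp HU to the stored 12-bit CT range [-1024, 4095]."""
    return np.clip(data, HU_MIN, HU_MAX)


def _affine_from_geometry(spacing, origin) -> np.ndarray:
    # on-disk axis order is (x, y, z); in-memory is (z, y, x)
    dz, dy, dx = spacing
    oz, oy, ox = origin
    aff = np.diag([dx, dy, dz, 1.0])
    aff[:3, 3] = [ox, oy, oz]
    return aff


def _geometry_from_affine(affine) -> Tuple[Tuple[float, float, float], Tuple[float, float, float]]:
    scales = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    dx, dy, dz = (float(s) for s in scales)
    ox, oy, oz = (float(v) for v in affine[:3, 3])
    return (dz, dy, dx), (oz, oy, ox)


def write_volume(vol: CTVolume, path: os.PathLike | str) -> None:
    """Write a volume as NIfTI-1, clamped to [-1024, 4095] and stored as int16.

    Lossless for integer HU inside the clamp range; fractional HU are rounded.
    """
    import nibabel as nib

    path = Path(path)
    data = np.rint(clamp_hu(vol.data)).astype(np.int16)
    img = nib.Nifti1Image(np.ascontiguousarray(data.transpose(2, 1, 0)), _affine_from_geometry(vol.spacing, vol.origin))
    try:
        nib.save(img, str(path))
    except OSError as exc:  # pragma: no cover - environment dependent
        raise FormatError(f"cannot write NIfTI volume to {path}: {exc}") from exc


def _read_nifti(path: Path) -> CTVolume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=np.float64).transpose(2, 1, 0)
    spacing, origin = _geometry_from_affine(img.affine)
    return CTVolume(data=data, spacing=spacing, origin=origin, case_id=path.stem.replace(".nii", ""))


def _read_dicom_series(path: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:
            raise FormatError(f"cannot read DICOM file {f}: {exc}") from exc
        if not hasattr(ds, "PixelData"):
            continue
        slices.append(ds)
    if not slices:
        raise FormatError(f"no DICOM image slices found under {path}")
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    if len(zs) > 1:
        dz_all = np.diff(zs)
        dz = float(dz_all.mean())
        if dz <= 0 or not np.allclose(dz_all, dz, atol=1e-3):
            raise GeometryError(f"inconsistent DICOM slice spacing under {path}: {dz_all}")
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    ref = slices[0]
    dy, dx = (float(v) for v in ref.PixelSpacing)
    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    data = np.stack(planes, axis=0)
    ox, oy, oz = (float(v) for v in ref.ImagePositionPatient)
    return CTVolume(data=data, spacing=(dz, dy, dx), origin=(oz, oy, ox), case_id=str(getattr(ref, "PatientID", path.name)))


def read_volume(path: os.PathLike | str, format: str = "nifti") -> CTVolume:
    """Read a CT volume.

    ``format="nifti"`` expects a .nii/.nii.gz file; ``format="dicom_series"``
    expects a directory of CT Image Storage files (rescale slope/intercept are
    applied so voxel values are HU).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such path: {path}")
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom_series":
        if not path.is_dir():
            raise FormatError(f"dicom_series expects a directory, got {path}")
        return _read_dicom_series(path)
    raise ValidationError(f"unknown format {format!r}; expected 'nifti' or 'dicom_series'")


def write_mask(mask: VoxelMask, path: os.PathLike | str) -> None:
    """Write a binary mask as uint8 {0, 1} NIfTI."""
    import nibabel as nib

    path = Path(path)
    img = nib.Nifti1Image(
        np.ascontiguousarray(mask.data.astype(np.uint8).transpose(2, 1, 0)),
        _affine_from_geometry(mask.spacing, mask.origin),
    )
    try:
        nib.save(img, str(path))
    except OSError as exc:  # pragma: no cover
        raise FormatError(f"cannot write mask to {path}: {exc}") from exc


def read_mask(path: os.PathLike | str, label: str) -> VoxelMask:
    """Read a binary mask; values other than {0, 1} raise ValidationError."""
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such path: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI mask {path}: {exc}") from exc
    data = np.asarray(img.get_fdata()).transpose(2, 1, 0)
    vals = np.unique(data)
    if not np.isin(vals, (0, 1)).all():
        raise ValidationError(f"mask file {path} has values outside {{0,1}}: {vals[:10]}")
    spacing, origin = _geometry_from_affine(img.affine)
    return VoxelMask(data=data.astype(bool), label=label, spacing=spacing, origin=origin)
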