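"""Label and intensity volume containers plus NIfTI / NRRD readers and writers.

Axis conventions: by default the last array axis indexes CT slices (cranial
to caudal with increasing index) and the first axis is the patient
left-right direction; both are stored on the volume and overridable.
Coordinates are 0-based voxel indices; physical distances are always derived
from ``spacing`` (mm per axis), which for typical planning CT is anisotropic
(e.g. 1.14 x 1.14 mm in-plane, 3 mm slice thickness).

NIfTI I/O uses nibabel; NRRD I/O uses SimpleITK. Round trips preserve the
array and spacing exactly. DICOM is deliberately unsupported.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .errors import FormatError, ValidationError
from .taxonomy import LevelTaxonomy

DEFAULT_SLICE_AXIS = 2
DEFAULT_LR_AXIS = 0

_INT_DTYPE = np.int16


def _normalize_spacing(spacing) -> tuple[float, float, float]:
    """Carry spacing at 32-bit precision (the NIfTI-1 header stores zooms as
    float32), so write-then-read round trips preserve spacing bitwise."""
    return tuple(float(np.float32(s)) for s in spacing)


@dataclass(frozen=True)
class LabelVolume:
    """A 3D integer label map with voxel spacing and axis conventions."""

    array: np.ndarray
    spacing: tuple[float, float, float]
    slice_axis: int = DEFAULT_SLICE_AXIS
    lr_axis: int = DEFAULT_LR_AXIS

    def __post_init__(self) -> None:
        if self.array.ndim != 3:
            raise FormatError(f"label volume must be 3D, got {self.array.ndim}D")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive components, got {self.spacing}")
        object.__setattr__(self, "spacing", _normalize_spacing(self.spacing))
        if self.slice_axis == self.lr_axis:
            raise ValidationError("slice_axis and lr_axis must differ")
        if not (0 <= self.slice_axis < 3 and 0 <= self.lr_axis < 3):
            raise ValidationError("axes must be in {0, 1, 2}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.array.shape

    def with_array(self, array: np.ndarray) -> "LabelVolume":
        return replace(self, array=array)

    def validate(self, taxonomy: LevelTaxonomy) -> "LabelVolume":
        """Check that every voxel value is background or a declared label."""
        present = np.unique(self.array)
        unknown = sorted(set(int(v) for v in present) - taxonomy.valid_values())
        if unknown:
            raise ValidationError(f"volume contains label values not in taxonomy: {unknown}")
        return self

    def __eq__(self, other: object) -> bool:  # dataclass default compares arrays ambiguously
        if not isinstance(other, LabelVolume):
            return NotImplemented
        return (
            np.array_equal(self.array, other.array)
            and self.spacing == other.spacing
            and self.slice_axis == other.slice_axis
            and self.lr_axis == other.lr_axis
        )


@dataclass(frozen=True)
class IntensityVolume:
    """A 3D scalar (CT-like) intensity grid with voxel spacing."""

    array: np.ndarray
    spacing: tuple[float, float, float]
    lr_axis: int = DEFAULT_LR_AXIS

    def __post_init__(self) -> None:
        if self.array.ndim != 3:
            raise FormatError(f"intensity volume must be 3D, got {self.array.ndim}D")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive components, got {self.spacing}")
        object.__setattr__(self, "spacing", _normalize_spacing(self.spacing))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntensityVolume):
            return NotImplemented
        return (
            np.array_equal(self.array, other.array)
            and self.spacing == other.spacing
            and self.lr_axis == other.lr_axis
        )


# ---------------------------------------------------------------------------
# raw 3D array + spacing I/O

def _is_nrrd(path: Path) -> bool:
    return path.suffix.lower() in {".nrrd", ".nhdr"}


def _read_array(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    if _is_nrrd(path):
        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise FormatError(f"{path}: expected a 3D image, got {img.GetDimension()}D")
        # SimpleITK arrays come back (z, y, x); transpose to (x, y, z)
        arr = sitk.GetArrayFromImage(img).T
        spacing = tuple(float(s) for s in img.GetSpacing())
        return arr, spacing
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a 3D image, got {arr.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return arr, spacing


def _write_array(arr: np.ndarray, spacing: tuple[float, float, float], path: Path) -> None:
    if _is_nrrd(path):
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr.T))
        img.SetSpacing(tuple(float(s) for s in spacing))
        sitk.WriteImage(img, str(path))
        return
    affine = np.diag([*spacing, 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def _as_int_array(arr: np.ndarray, path: Path) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(_INT_DTYPE, copy=False)
    if np.issubdtype(arr.dtype, np.floating):
        rounded = np.rint(arr)
        if not np.array_equal(rounded, arr):
            raise FormatError(f"{path}: label image contains non-integer values")
        return rounded.astype(_INT_DTYPE)
    raise FormatError(f"{path}: unsupported dtype {arr.dtype} for a label image")


def read_label_volume(
    path: str | Path,
    taxonomy: LevelTaxonomy,
    slice_axis: int = DEFAULT_SLICE_AXIS,
    lr_axis: int = DEFAULT_LR_AXIS,
) -> LabelVolume:
    """Read a NIfTI or NRRD label map and validate it against a taxonomy."""
    path = Path(path)
    arr, spacing = _read_array(path)
    vol = LabelVolume(_as_int_array(arr, path), spacing, slice_axis=slice_axis, lr_axis=lr_axis)
    return vol.validate(taxonomy)


def write_label_volume(volume: LabelVolume, path: str | Path) -> None:
    """Write a label volume; ``read_label_volume`` round-trips array and spacing exactly."""
    path = Path(path)
    _write_array(volume.array.astype(_INT_DTYPE, copy=False), volume.spacing, path)


def read_intensity_volume(
    path: str | Path, lr_axis: int = DEFAULT_LR_AXIS
) -> IntensityVolume:
    path = Path(path)
    arr, spacing = _read_array(path)
    return IntensityVolume(np.asarray(arr, dtype=np.float32), spacing, lr_axis=lr_axis)


def write_intensity_volume(volume: IntensityVolume, path: str | Path) -> None:
    _write_array(np.asarray(volume.array, dtype=np.float32), volume.spacing, Path(path))
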