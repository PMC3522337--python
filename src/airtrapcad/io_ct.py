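"""CT volume and lung-mask containers plus DICOM/NIfTI I/O.

Axis convention used throughout the package:

* ``voxels[slice, row, col]`` with slice 0 at the lung apex (most superior),
  rows running anterior to posterior and columns left to right;
* ``spacing = (dz, dy, dx)`` in millimetres, matching the voxel axes.

All areas and volumes elsewhere in the package are computed in physical
units via ``spacing``, never as raw voxel counts, because the inspiration
and expiration scans of one subject may have different slice counts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Tuple

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .errors import FormatError, InputError, MetadataError

INSPIRATION = "inspiration"
EXPIRATION = "expiration"
PHASES = (INSPIRATION, EXPIRATION)


def _check_phase(phase: str) -> str:
    if phase not in PHASES:
        raise ParameterErrorFromPhase(phase)
    return phase


class ParameterErrorFromPhase(InputError):
    def __init__(self, phase: str):
        super().__init__(f"phase must be one of {PHASES}, got {phase!r}")


@dataclass
class CTVolume:
    """A 3-D scalar field in Hounsfield units with physical spacing.

    Parameters
    ----------
    voxels
        3-D array (slice, row, col) of HU values; slice 0 = apex.
    spacing
        (dz, dy, dx) in mm, all strictly positive.
    phase
        ``"inspiration"`` or ``"expiration"``.
    subject_id
        Opaque identifier carried through the pipeline.
    """

    voxels: np.ndarray
    spacing: Tuple[float, float, float]
    phase: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise InputError("CTVolume voxels must be a non-empty 3-D array")
        if not np.all(np.isfinite(self.voxels)):
            raise InputError("CTVolume contains non-finite HU values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InputError(f"spacing must be 3 positive numbers, got {self.spacing}")
        _check_phase(self.phase)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx


@dataclass
class LungMask:
    """Binary lung mask aligned voxel-for-voxel with its source CTVolume."""

    voxels: np.ndarray
    spacing: Tuple[float, float, float]
    phase: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise InputError("LungMask voxels must be a non-empty 3-D array")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise InputError("LungMask values must be 0/1")
        self.voxels = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InputError(f"spacing must be 3 positive numbers, got {self.spacing}")
        _check_phase(self.phase)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def volume_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return float(self.voxels.sum()) * dz * dy * dx


# --------------------------------------------------------------------------
# NIfTI
#
# Internally (slice, row, col) = (S->I, A->P, L->R).  The canonical NIfTI
# orientation is RAS with array axes (i, j, k) = (L->R, P->A, I->S), so the
# mapping is a transpose plus a flip of the row and slice axes.

def _to_ras(voxels: np.ndarray) -> np.ndarray:
    return np.transpose(voxels, (2, 1, 0))[:, ::-1, ::-1]


def _from_ras(data: np.ndarray) -> np.ndarray:
    return np.transpose(data[:, ::-1, ::-1], (2, 1, 0))


def write_volume(v: "CTVolume | LungMask", path: "str | os.PathLike") -> None:
    """Write a volume or mask as NIfTI-1 with spacing in the header.

    HU volumes are stored as float32, masks as unsigned 8-bit.
    """
    path = os.fspath(path)
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise InputError(f"parent directory does not exist: {parent}")
    dz, dy, dx = v.spacing
    data = _to_ras(v.voxels)
    affine = np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(np.ascontiguousarray(data), affine)
    img.header.set_zooms((dx, dy, dz))
    try:
        nib.save(img, path)
    except OSError as exc:  # unwritable target
        raise InputError(f"cannot write {path}: {exc}") from exc


def _read_nifti(path: str, phase: str, subject_id: str):
    try:
        img = nib.load(path)
    except Exception as exc:
        raise InputError(f"cannot read NIfTI {path}: {exc}") from exc
    can = nib.as_closest_canonical(img)
    zooms = can.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise MetadataError(f"non-positive voxel spacing in NIfTI header: {zooms}")
    data = np.asanyarray(can.dataobj)
    voxels = _from_ras(data)
    dx, dy, dz = (float(z) for z in zooms)
    return voxels, (dz, dy, dx)


# --------------------------------------------------------------------------
# DICOM series

_TAG_PIXEL_SPACING = "0028|0030"


def _read_dicom_series(path: str, phase: str):
    reader = sitk.ImageSeriesReader()
    series_ids = reader.GetGDCMSeriesIDs(path)
    if len(series_ids) == 0:
        raise InputError(f"no DICOM series found in {path}")
    if len(series_ids) > 1:
        raise FormatError(
            f"directory {path} contains {len(series_ids)} DICOM series; expected one"
        )
    files = reader.GetGDCMSeriesFileNames(path, series_ids[0])

    probe = sitk.ImageFileReader()
    probe.SetFileName(files[0])
    probe.LoadPrivateTagsOn()
    probe.ReadImageInformation()
    if not probe.HasMetaDataKey(_TAG_PIXEL_SPACING):
        raise MetadataError("missing DICOM PixelSpacing (0028,0030)")

    reader.SetFileNames(files)
    img = reader.Execute()  # rescale slope/intercept applied by GDCM
    arr = sitk.GetArrayFromImage(img).astype(np.float32)  # (z, y, x)
    dx, dy, dz = img.GetSpacing()
    direction = img.GetDirection()
    # LPS slice-axis direction: +z component of the third column points
    # superior, meaning increasing index runs inferior->superior -> flip so
    # that slice 0 is the most superior slice.
    if direction[8] > 0:
        arr = arr[::-1]
    return arr, (float(dz), float(dy), float(dx))


def read_volume(path: "str | os.PathLike", phase: str, subject_id: str = "") -> CTVolume:
    """Read a CT volume from a DICOM series directory or a NIfTI file.

    Slices are returned superior -> inferior regardless of on-disk order and
    DICOM rescale slope/intercept is applied, so values are Hounsfield units.
    """
    _check_phase(phase)
    path = os.fspath(path)
    if os.path.isdir(path):
        voxels, spacing = _read_dicom_series(path, phase)
    elif os.path.isfile(path):
        voxels, spacing = _read_nifti(path, phase, subject_id)
    else:
        raise InputError(f"no such file or directory: {path}")
    return CTVolume(voxels=voxels, spacing=spacing, phase=phase, subject_id=subject_id)


def read_mask(path: "str | os.PathLike", phase: str, subject_id: str = "") -> LungMask:
    """Read a binary lung mask from a NIfTI file (values coerced to 0/1)."""
    _check_phase(phase)
    path = os.fspath(path)
    if not os.path.isfile(path):
        raise InputError(f"no such file: {path}")
    voxels, spacing = _read_nifti(path, phase, subject_id)
    return LungMask(
        voxels=(np.asarray(voxels) > 0.5).astype(np.uint8),
        spacing=spacing,
        phase=phase,
        subject_id=subject_id,
    )
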