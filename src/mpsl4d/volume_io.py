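"""Spatial data model and file I/O for per-phase CT volumes and masks.

The in-memory convention is fixed regardless of on-disk layout:

* arrays are indexed ``[i, j, k]`` along physical axes ``(x, y, z)`` with
  ``z`` the slice axis; readers reorder as needed;
* voxel indices are 0-based and the physical position of voxel (i,j,k)
  is ``origin + (i·dx, j·dy, k·dz)`` (node-at-voxel-center);
* intensities are in Hounsfield units (DICOM rescale slope/intercept
  applied on read).

Supported inputs are a directory of DICOM slices per phase or one NIfTI
file per phase.  Masks are written to NIfTI as unsigned 8-bit {0,1};
trajectories go to CSV with the fixed header
``phase,cog_x_mm,cog_y_mm,cog_z_mm,volume_cc``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FormatError, VolumeIOError
from .motion_metrics import Trajectory

__all__ = [
    "PhaseVolume",
    "Series4D",
    "BinaryMask",
    "read_phase_volume",
    "write_phase_volume",
    "read_mask",
    "write_mask",
    "read_trajectory",
    "write_trajectory",
    "VALID_PHASE_LABELS",
]

VALID_PHASE_LABELS = tuple(range(0, 100, 10))


def _check_spacing(spacing):
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ConfigurationError(
            f"spacing must be three strictly positive components, got {spacing}"
        )
    return spacing


@dataclass
class PhaseVolume:
    """One 3-D scalar image (HU) at one breathing phase.

    ``phase_label`` is the percentage of the breathing cycle (0–90 in
    steps of 10) when the volume belongs to a 4-D series; it may be None
    for a standalone volume.
    """

    voxels: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    phase_label: Optional[int] = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ConfigurationError(
                f"voxel array must be 3-D, got shape {self.voxels.shape}"
            )
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.phase_label is not None and self.phase_label not in VALID_PHASE_LABELS:
            raise ConfigurationError(
                f"phase_label must be in {VALID_PHASE_LABELS}, got {self.phase_label}"
            )

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class Series4D:
    """An ordered 4-D series: one PhaseVolume per breathing phase."""

    phases: List[PhaseVolume]

    def __post_init__(self):
        if not self.phases:
            raise ConfigurationError("a 4-D series needs at least one phase")
        ref = self.phases[0]
        labels = []
        for p in self.phases:
            if p.shape != ref.shape or not np.allclose(p.spacing, ref.spacing):
                raise ConfigurationError(
                    "all phases must share identical dimensions and spacing"
                )
            if p.phase_label is None:
                raise ConfigurationError("every phase in a series needs a phase_label")
            labels.append(p.phase_label)
        if any(b <= a for a, b in zip(labels, labels[1:])):
            raise ConfigurationError(
                f"phase labels must be strictly increasing, got {labels}"
            )

    def __len__(self) -> int:
        return len(self.phases)

    @property
    def phase_labels(self) -> List[int]:
        return [p.phase_label for p in self.phases]


@dataclass
class BinaryMask:
    """3-D boolean voxel set aligned to a PhaseVolume grid."""

    voxels: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ConfigurationError(
                f"mask array must be 3-D, got shape {self.voxels.shape}"
            )
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_cc(self) -> float:
        return self.voxel_count * float(np.prod(self.spacing)) / 1000.0

    def replace_voxels(self, voxels: np.ndarray) -> "BinaryMask":
        """A new mask on the same grid with different voxels."""
        return BinaryMask(voxels, self.spacing, self.origin)

    @classmethod
    def empty_like(cls, vol: PhaseVolume) -> "BinaryMask":
        return cls(np.zeros(vol.shape, dtype=bool), vol.spacing, vol.origin)


# ---------------------------------------------------------------------------
# NIfTI

def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def _load_nifti(path: Path):
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise VolumeIOError(f"no such file: {path}") from None
    except Exception as exc:  # nibabel raises several error types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return data, zooms, origin


def _read_nifti_volume(path: Path, phase_label=None) -> PhaseVolume:
    data, zooms, origin = _load_nifti(path)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return PhaseVolume(data.astype(np.float32), zooms, origin, phase_label)


# ---------------------------------------------------------------------------
# DICOM

def _read_dicom_dir(path: Path, phase_label=None) -> PhaseVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise VolumeIOError(f"no files in DICOM directory {path}")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:
            raise FormatError(f"cannot read DICOM file {f}: {exc}") from exc
        slices.append((f, ds))

    def _orient(ds):
        return tuple(float(v) for v in getattr(ds, "ImageOrientationPatient",
                                               (1, 0, 0, 0, 1, 0)))

    def _pix(ds):
        return tuple(float(v) for v in getattr(ds, "PixelSpacing", (1.0, 1.0)))

    ref_orient, ref_pix = _orient(slices[0][1]), _pix(slices[0][1])
    for f, ds in slices[1:]:
        if _orient(ds) != ref_orient:
            raise FormatError(f"mixed slice orientation in {path} (first at {f})")
        if _pix(ds) != ref_pix:
            raise FormatError(f"mixed in-plane spacing in {path} (first at {f})")

    def _zpos(ds):
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=lambda fd: _zpos(fd[1]))
    planes = []
    for f, ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    stack = np.stack(planes, axis=0)          # (z, rows=y, cols=x)
    vox = np.transpose(stack, (2, 1, 0))      # (x, y, z)

    zpos = [_zpos(ds) for _, ds in slices]
    if len(zpos) > 1:
        dz = float(np.median(np.diff(zpos)))
        if dz <= 0:
            dz = float(getattr(slices[0][1], "SliceThickness", 1.0))
    else:
        dz = float(getattr(slices[0][1], "SliceThickness", 1.0))
    dy, dx = ref_pix  # DICOM PixelSpacing is (row, col) = (y, x)
    ipp0 = getattr(slices[0][1], "ImagePositionPatient", (0.0, 0.0, 0.0))
    origin = tuple(float(v) for v in ipp0)
    return PhaseVolume(vox, (dx, dy, dz), origin, phase_label)


# ---------------------------------------------------------------------------
# Public readers / writers

def read_phase_volume(path, format: str = None, phase_label: int = None) -> PhaseVolume:
    """Read one 3-D phase volume from a DICOM directory or a NIfTI file.

    ``format`` is ``"dicom-dir"`` or ``"nifti"``; when omitted it is
    inferred from the path (directory → DICOM, file → NIfTI).
    """
    p = Path(path)
    if not p.exists():
        raise VolumeIOError(f"no such path: {p}")
    if format is None:
        format = "dicom-dir" if p.is_dir() else "nifti"
    if format == "dicom-dir":
        if not p.is_dir():
            raise VolumeIOError(f"dicom-dir format needs a directory, got {p}")
        return _read_dicom_dir(p, phase_label)
    if format == "nifti":
        return _read_nifti_volume(p, phase_label)
    raise ConfigurationError(f"format must be 'dicom-dir' or 'nifti', got {format!r}")


def write_phase_volume(vol: PhaseVolume, path) -> Path:
    """Write a phase volume to NIfTI (float32 HU)."""
    p = Path(path)
    if not p.parent.is_dir():
        raise VolumeIOError(f"parent directory does not exist: {p.parent}")
    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float32),
                          _affine(vol.spacing, vol.origin))
    nib.save(img, str(p))
    return p


def read_mask(path) -> BinaryMask:
    """Read a binary mask from NIfTI (any nonzero voxel is foreground)."""
    data, zooms, origin = _load_nifti(Path(path))
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D mask, got shape {data.shape}")
    return BinaryMask(data > 0, zooms, origin)


def write_mask(mask: BinaryMask, path) -> Path:
    """Write a binary mask to NIfTI as unsigned 8-bit {0,1}."""
    p = Path(path)
    if not p.parent.is_dir():
        raise VolumeIOError(f"parent directory does not exist: {p.parent}")
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8),
                          _affine(mask.spacing, mask.origin))
    nib.save(img, str(p))
    return p


TRAJECTORY_COLUMNS = ["phase", "cog_x_mm", "cog_y_mm", "cog_z_mm", "volume_cc"]


def write_trajectory(traj: Trajectory, path) -> Path:
    """Write a trajectory as CSV with the fixed column order."""
    p = Path(path)
    if not p.parent.is_dir():
        raise VolumeIOError(f"parent directory does not exist: {p.parent}")
    traj.to_dataframe()[TRAJECTORY_COLUMNS].to_csv(p, index=False)
    return p


def read_trajectory(path) -> Trajectory:
    p = Path(path)
    if not p.exists():
        raise VolumeIOError(f"no such file: {p}")
    df = pd.read_csv(p)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{p}: missing trajectory columns {missing}")
    return Trajectory.from_dataframe(df)
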