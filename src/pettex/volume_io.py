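"""NIfTI input/output for PET volumes and lesion masks, plus SUV conversion.

A :class:`PetVolume` is a 3D grid of standardized uptake values (SUV,
dimensionless) with voxel spacing in millimetres; a :class:`LesionMask` is a
boolean grid sharing the geometry of its companion volume.  Storage format is
NIfTI-1 (``.nii`` / ``.nii.gz``); masks are stored as 8-bit integer volumes
with 0/1 values.  Voxel indices are 0-based and a voxel's physical center is
``origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "PetVolume",
    "LesionMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "activity_to_suv",
]


def _as_spacing(spacing) -> tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing)
    if len(sp) != 3:
        raise ValueError(f"spacing must have 3 components, got {len(sp)}")
    if any(s <= 0 for s in sp):
        raise ValueError(f"all spacing components must be > 0, got {sp}")
    return sp


@dataclass
class PetVolume:
    """A 3D SUV-valued image grid.

    Parameters
    ----------
    values
        3D array of SUV values; finite and non-negative.
    spacing
        Voxel spacing ``(dx, dy, dz)`` in mm, all positive.
    origin
        Physical coordinate of the center of voxel ``(0, 0, 0)`` in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.values.ndim}D data")
        if any(n < 1 for n in self.values.shape):
            raise ValueError(f"grid dimensions must be >= 1, got {self.values.shape}")
        self.spacing = _as_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if not np.all(np.isfinite(self.values)):
            idx = tuple(int(i) for i in np.argwhere(~np.isfinite(self.values))[0])
            raise ValueError(f"volume contains non-finite value at voxel {idx}")
        if np.any(self.values < 0):
            idx = tuple(int(i) for i in np.argwhere(self.values < 0)[0])
            raise ValueError(f"volume contains negative value at voxel {idx}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class LesionMask:
    """Boolean VOI grid with the same geometry as its companion volume."""

    flags: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags).astype(bool)
        if self.flags.ndim != 3:
            raise ValueError(f"mask must be 3D, got {self.flags.ndim}D data")
        self.spacing = _as_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.flags.shape

    @property
    def n_voxels(self) -> int:
        return int(self.flags.sum())

    def check_compatible(self, other: "PetVolume | LesionMask") -> None:
        """Raise if ``other`` does not share this mask's grid geometry."""
        other_shape = other.shape
        if other_shape != self.shape:
            raise ValueError(
                f"geometry mismatch: shape {self.shape} vs {other_shape}"
            )
        if not np.allclose(self.spacing, other.spacing):
            raise ValueError(
                f"geometry mismatch: spacing {self.spacing} vs {other.spacing}"
            )


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | Path) -> PetVolume:
    """Read a 3D SUV volume from a NIfTI file.

    Spacing is taken from the file header (``pixdim``); values are cast to
    floating point.  Raises a descriptive error for missing files, non-3D
    data, non-positive spacing, or negative voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"volume must be 3D, got {data.ndim}D data in {path}")
    spacing = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return PetVolume(values=data.astype(float), spacing=spacing, origin=origin)


def write_volume(volume: PetVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(
        volume.values.astype(np.float32), _affine(volume.spacing, volume.origin)
    )
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> LesionMask:
    """Read a 0/1 NIfTI volume as a boolean lesion mask."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"mask must be 3D, got {data.ndim}D data in {path}")
    return LesionMask(flags=data > 0, spacing=img.header.get_zooms()[:3])


def write_mask(mask: LesionMask, path: str | Path) -> None:
    img = nib.Nifti1Image(
        mask.flags.astype(np.uint8), _affine(mask.spacing, (0.0, 0.0, 0.0))
    )
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def activity_to_suv(
    concentration: np.ndarray,
    injected_dose_mbq: float,
    body_weight_kg: float,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> PetVolume:
    """Convert an activity-concentration grid (kBq/mL) to SUV.

    SUV = concentration [kBq/mL] x body weight [g] / injected dose [kBq];
    with dose in MBq and weight in kg the unit factors of 1000 cancel, so
    SUV = concentration x weight / dose.  No decay correction is applied
    (scanners apply it upstream).
    """
    if injected_dose_mbq <= 0:
        raise ValueError(f"injected dose must be > 0 MBq, got {injected_dose_mbq}")
    if body_weight_kg <= 0:
        raise ValueError(f"body weight must be > 0 kg, got {body_weight_kg}")
    conc = np.asarray(concentration, dtype=float)
    suv = conc * (body_weight_kg * 1000.0) / (injected_dose_mbq * 1000.0)
    return PetVolume(values=suv, spacing=spacing, origin=origin)
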