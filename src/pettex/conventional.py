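"""Conventional SUV metrics: SUVmax, SUVpeak, SUVmean, MTV and TLG.

SUVpeak is the mean SUV inside a 1 cm^3 sphere centered on the hottest VOI
voxel; MTV (metabolic tumor volume) is the physical VOI volume in cm^3; TLG
(total lesion glycolysis) is SUVmean x MTV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import LesionMask, PetVolume

__all__ = ["ConventionalMetrics", "suv_stats", "suv_peak", "mtv", "tlg",
           "compute_conventional", "CONVENTIONAL_NAMES"]

#: Column names used in per-lesion feature tables, in canonical order.
CONVENTIONAL_NAMES = ("SUVmax", "SUVpeak", "SUVmean", "MTV_cm3", "TLG")


@dataclass(frozen=True)
class ConventionalMetrics:
    suv_max: float
    suv_peak: float
    suv_mean: float
    mtv_cm3: float
    tlg: float

    def as_dict(self) -> dict[str, float]:
        return {
            "SUVmax": self.suv_max,
            "SUVpeak": self.suv_peak,
            "SUVmean": self.suv_mean,
            "MTV_cm3": self.mtv_cm3,
            "TLG": self.tlg,
        }


def _require_nonempty(mask: LesionMask) -> None:
    if mask.n_voxels == 0:
        raise ValueError("empty mask: no voxels to evaluate")


def suv_stats(volume: PetVolume, mask: LesionMask) -> tuple[float, float]:
    """Return (SUVmax, SUVmean) of the values inside the mask."""
    mask.check_compatible(volume)
    _require_nonempty(mask)
    vals = volume.values[mask.flags]
    return float(vals.max()), float(vals.mean())


def suv_peak(
    volume: PetVolume, mask: LesionMask, sphere_volume_cm3: float = 1.0
) -> float:
    """Mean SUV in a sphere of ``sphere_volume_cm3`` around the hottest voxel.

    The sphere (radius ``(3V / 4 pi)^(1/3)``, about 6.2 mm for 1 cm^3) is
    centered on the physical center of the mask's maximum voxel; membership
    is by voxel center, the sphere is clipped to the grid but *not* to the
    mask.  If the sphere captures no voxel center beyond the hot voxel, the
    value of the hot voxel itself is returned.
    """
    mask.check_compatible(volume)
    _require_nonempty(mask)
    if sphere_volume_cm3 <= 0:
        raise ValueError("sphere volume must be positive")

    vals = volume.values
    masked = np.where(mask.flags, vals, -np.inf)
    hot = np.unravel_index(np.argmax(masked), vals.shape)
    radius_mm = (3.0 * sphere_volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)

    spacing = np.asarray(volume.spacing)
    reach = np.floor(radius_mm / spacing).astype(int)
    sel_vals = []
    for di in range(-reach[0], reach[0] + 1):
        for dj in range(-reach[1], reach[1] + 1):
            for dk in range(-reach[2], reach[2] + 1):
                i, j, k = hot[0] + di, hot[1] + dj, hot[2] + dk
                if not (0 <= i < vals.shape[0] and 0 <= j < vals.shape[1]
                        and 0 <= k < vals.shape[2]):
                    continue
                dist = np.sqrt(
                    (di * spacing[0]) ** 2
                    + (dj * spacing[1]) ** 2
                    + (dk * spacing[2]) ** 2
                )
                if dist <= radius_mm:
                    sel_vals.append(vals[i, j, k])
    if not sel_vals:  # sphere smaller than one voxel
        return float(vals[hot])
    return float(np.mean(sel_vals))


def mtv(mask: LesionMask) -> float:
    """Metabolic tumor volume in cm^3: voxel count x voxel volume / 1000."""
    _require_nonempty(mask)
    dx, dy, dz = mask.spacing
    return mask.n_voxels * dx * dy * dz / 1000.0


def tlg(volume: PetVolume, mask: LesionMask) -> float:
    """Total lesion glycolysis: SUVmean x MTV (SUV cm^3)."""
    _, mean = suv_stats(volume, mask)
    return mean * mtv(mask)


def compute_conventional(volume: PetVolume, mask: LesionMask) -> ConventionalMetrics:
    smax, smean = suv_stats(volume, mask)
    vol = mtv(mask)
    return ConventionalMetrics(
        suv_max=smax,
        suv_peak=suv_peak(volume, mask),
        suv_mean=smean,
        mtv_cm3=vol,
        tlg=smean * vol,
    )
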