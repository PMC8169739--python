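"""Percentile-window gray-level discretization of a VOI.

In-mask SUV values are linearly rescaled between the VOI's 1st and 99th
percentiles into a fixed number of bins (default 64).  Values outside the
percentile window are clamped into the first and last bin rather than
excluded, so every VOI voxel carries a gray level and the voxel set is
identical for all downstream texture matrices.  Because percentiles
transform identically, the levels — and therefore all texture features —
are invariant to positive affine rescaling of the SUVs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import LesionMask, PetVolume

__all__ = ["DiscretizedVoi", "discretize"]


@dataclass
class DiscretizedVoi:
    """Masked integer gray-level grid: 0 outside the VOI, 1..n_levels inside."""

    levels: np.ndarray
    mask: LesionMask
    n_levels: int
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int32)
        inside = self.levels[self.mask.flags]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("in-mask levels must lie in [1, n_levels]")
        if np.any(self.levels[~self.mask.flags] != 0):
            raise ValueError("out-of-mask levels must be 0")

    @property
    def n_voxels(self) -> int:
        return self.mask.n_voxels

    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask.flags]


def discretize(
    volume: PetVolume,
    mask: LesionMask,
    n_levels: int = 64,
    p_lo: float = 1.0,
    p_hi: float = 99.0,
) -> DiscretizedVoi:
    """Map in-mask intensities to gray levels 1..n_levels.

    With ``P_lo``, ``P_hi`` the ``p_lo``-th and ``p_hi``-th percentiles of
    the in-mask values (linear interpolation between order statistics), a
    value ``x`` maps to ``clamp(floor((x - P_lo) / (P_hi - P_lo) * n_levels)
    + 1, 1, n_levels)``.  If the window is degenerate (``P_hi == P_lo``) all
    in-mask voxels map to level 1.
    """
    mask.check_compatible(volume)
    if mask.n_voxels == 0:
        raise ValueError("empty mask: nothing to discretize")
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    if not (0 <= p_lo < p_hi <= 100):
        raise ValueError(f"need 0 <= p_lo < p_hi <= 100, got ({p_lo}, {p_hi})")

    inside = volume.values[mask.flags]
    lo, hi = np.percentile(inside, [p_lo, p_hi])
    levels = np.zeros(volume.shape, dtype=np.int32)
    if hi == lo:
        levels[mask.flags] = 1
    else:
        scaled = np.floor((inside - lo) / (hi - lo) * n_levels).astype(np.int64) + 1
        levels[mask.flags] = np.clip(scaled, 1, n_levels)
    return DiscretizedVoi(
        levels=levels, mask=mask, n_levels=int(n_levels), spacing=volume.spacing
    )
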