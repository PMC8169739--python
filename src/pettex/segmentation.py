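"""Fixed-fraction VOI delineation.

The lesion volume of interest is the 26-connected set of voxels whose SUV is
at least a fixed fraction (default 40%) of the lesion's SUVmax, restricted to
an operator-supplied search region and optionally trimmed by an exclusion
mask covering physiological uptake (myocardium, great vessels, ...).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .volume_io import LesionMask, PetVolume

__all__ = ["threshold_voi", "apply_exclusion", "CONNECTIVITY_STRUCTURE"]

logger = logging.getLogger(__name__)

#: 26-neighbourhood structuring element used for VOI connectivity.
CONNECTIVITY_STRUCTURE = np.ones((3, 3, 3), dtype=bool)


def threshold_voi(
    volume: PetVolume, search_mask: LesionMask, fraction: float = 0.40
) -> LesionMask:
    """Delineate a VOI at ``fraction`` x SUVmax inside ``search_mask``.

    SUVmax is the maximum SUV inside the search region.  The result is the
    26-connected component, containing an SUVmax voxel, of the set of search
    voxels with value >= fraction * SUVmax (ties at the threshold are kept).
    If several voxels share the maximum and fall in different components, the
    component of the lexicographically first maximum voxel is taken and a
    warning is logged.
    """
    search_mask.check_compatible(volume)
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"threshold fraction must be in (0, 1], got {fraction}")
    if search_mask.n_voxels == 0:
        raise ValueError("empty search mask: nothing to segment")

    vals = volume.values
    suv_max = float(vals[search_mask.flags].max())
    if suv_max <= 0.0:
        raise ValueError("degenerate threshold: volume is all-zero inside search mask")

    candidates = search_mask.flags & (vals >= fraction * suv_max)
    labels, n_components = ndimage.label(candidates, structure=CONNECTIVITY_STRUCTURE)

    max_voxels = np.argwhere(search_mask.flags & (vals == suv_max))
    # np.argwhere returns lexicographic index order; the first row is the
    # deterministic tie-break.
    first_max = tuple(max_voxels[0])
    if len(max_voxels) > 1:
        comp_ids = {int(labels[tuple(v)]) for v in max_voxels}
        if len(comp_ids) > 1:
            logger.warning(
                "multiple SUVmax voxels fall in %d distinct components; "
                "keeping the component of voxel %s",
                len(comp_ids),
                first_max,
            )
    result = labels == labels[first_max]
    return LesionMask(flags=result, spacing=search_mask.spacing)


def apply_exclusion(mask: LesionMask, exclusion: LesionMask) -> LesionMask:
    """Remove physiological-uptake voxels from a VOI: ``mask AND NOT exclusion``."""
    mask.check_compatible(exclusion)
    result = mask.flags & ~exclusion.flags
    if not result.any():
        raise ValueError("empty VOI: exclusion mask removed every voxel")
    return LesionMask(flags=result, spacing=mask.spacing)
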