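"""Shared fixtures: small volumes, random discretized VOIs, and the
session-wide synthetic cohort used by the end-to-end discrimination tests."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from pettex.discretization import DiscretizedVoi
from pettex.phantoms import iter_cohort
from pettex.segmentation import threshold_voi
from pettex.volume_io import LesionMask, PetVolume

SPACING = (3.9, 3.9, 2.0)


def make_volume(values, spacing=SPACING) -> PetVolume:
    return PetVolume(values=np.asarray(values, dtype=float), spacing=spacing)


def full_mask(volume: PetVolume) -> LesionMask:
    return LesionMask(flags=np.ones(volume.shape, dtype=bool), spacing=volume.spacing)


def make_dvoi(levels, n_levels, spacing=SPACING) -> DiscretizedVoi:
    levels = np.asarray(levels, dtype=np.int32)
    if levels.ndim == 2:
        levels = levels[:, :, None]
    mask = LesionMask(flags=levels > 0, spacing=spacing)
    return DiscretizedVoi(levels=levels, mask=mask, n_levels=n_levels, spacing=spacing)


def random_dvoi(rng, max_shape=(6, 6, 4), max_levels=8) -> DiscretizedVoi:
    """Small random discretized VOI with a random (nonempty) mask."""
    shape = tuple(int(rng.integers(2, m + 1)) for m in max_shape)
    n_levels = int(rng.integers(2, max_levels + 1))
    mask = rng.random(shape) < rng.uniform(0.4, 0.95)
    if not mask.any():
        mask.flat[int(rng.integers(mask.size))] = True
    levels = np.where(mask, rng.integers(1, n_levels + 1, size=shape), 0)
    return make_dvoi(levels.astype(np.int32), n_levels)


@pytest.fixture(scope="session")
def cohort_summary():
    """Features + segmentation-overlap summary of the default 32/31 cohort
    at the shipped seed, computed in one streaming pass."""
    import pandas as pd

    from pettex.pipeline import extract_lesion

    rows = []
    tumor_dice = []
    eq_diam = {"tumor": [], "pneumonitis": []}
    for rec in iter_cohort(n_tumor=32, n_rp=31, master_seed=0):
        voi = threshold_voi(rec.volume, rec.mask, fraction=0.40)
        inter = int((voi.flags & rec.mask.flags).sum())
        if rec.label == "tumor":
            tumor_dice.append(2.0 * inter / (voi.n_voxels + rec.mask.n_voxels))
        voxel_mm3 = float(np.prod(rec.mask.spacing))
        eq_diam[rec.label].append(
            (6.0 * rec.mask.n_voxels * voxel_mm3 / np.pi) ** (1.0 / 3.0)
        )
        rows.append(
            {"lesion_id": rec.lesion_id, "label": rec.label,
             **extract_lesion(rec.volume, rec.mask)}
        )
    return {
        "features": pd.DataFrame(rows),
        "tumor_dice": np.asarray(tumor_dice),
        "eq_diam": {k: np.asarray(v) for k, v in eq_diam.items()},
    }
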