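"""Texture-matrix families and the 56-parameter feature vector.

Seven families are computed from one discretized VOI:

* ``NGLCM`` — normalized gray-level co-occurrence matrices over the 4
  in-plane directions (pairs pooled across axial slices); 7 features
  (Uniformity, Entropy, Dissimilarity, Contrast, Homogeneity, Inverse
  Difference Moment, Correlation) aggregated as mean and max over the 4
  directions (14 parameters).
* ``NGLCM3D`` — 13-direction volumetric co-occurrence matrices; 6 features
  per direction, mean/max aggregation (12 parameters).
* ``NGLCM3DMean`` — element-wise average of the 13 volumetric matrices,
  features computed once (6 parameters).
* ``GLRLM`` — gray-level run-length matrices over the 13 volumetric
  directions; 5 features, mean/max aggregation (10 parameters).
* ``GLSZM`` — gray-level size-zone matrix, zones being 26-connected
  equal-level components (7 parameters).
* ``NGTDM`` — neighborhood gray-tone difference components over the
  26-neighborhood; Amadasun-King coarseness, contrast, busyness,
  complexity, strength (5 parameters).
* ``SUVHistogram`` — gray-level histogram variance and entropy
  (2 parameters).

Gray-level indices ``i``, ``j`` in every formula are the 1-based bin
numbers, not SUV values; all entropies are base 2.  Co-occurrence distance
is 1 voxel (Chebyshev) in index space; anisotropic spacing is ignored for
offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .conventional import CONVENTIONAL_NAMES, compute_conventional
from .discretization import DiscretizedVoi, discretize
from .volume_io import LesionMask, PetVolume

__all__ = [
    "CooccurrenceMatrix",
    "RunLengthMatrix",
    "SizeZoneMatrix",
    "NgtdmComponents",
    "ExtractionConfig",
    "DIRECTIONS_3D",
    "DIRECTIONS_2D",
    "FAMILIES",
    "TEXTURE_FEATURE_NAMES",
    "ALL_FEATURE_NAMES",
    "compute_glcm",
    "glcm_features",
    "aggregate_directions",
    "compute_glrlm",
    "glrlm_features",
    "compute_glszm",
    "glszm_features",
    "compute_ngtdm",
    "ngtdm_features",
    "histogram_features",
    "extract_texture",
    "extract_all",
]

logger = logging.getLogger(__name__)

NGTDM_EPS = 1e-6
NGTDM_COARSENESS_CAP = 1e6


def _unique_directions_3d() -> tuple[tuple[int, int, int], ...]:
    dirs = []
    for dz in (0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                # keep one representative of each +/- offset pair
                if dz > 0 or (dz == 0 and dy > 0) or (dz == 0 and dy == 0 and dx > 0):
                    dirs.append(d)
    return tuple(dirs)


#: The 13 unique 3D offsets (one per +/- pair of the 26-neighborhood).
DIRECTIONS_3D = _unique_directions_3d()
#: The 4 unique in-plane (axial, dz = 0) offsets.
DIRECTIONS_2D = tuple(d for d in DIRECTIONS_3D if d[2] == 0)
assert len(DIRECTIONS_3D) == 13 and len(DIRECTIONS_2D) == 4

FAMILIES = (
    "GLRLM",
    "GLSZM",
    "NGLCM3D",
    "NGLCM3DMean",
    "NGLCM",
    "NGTDM",
    "SUVHistogram",
)

_GLRLM_NAMES = (
    "ShortRunsEmphasis",
    "LongRunsEmphasis",
    "GrayLevelNonuniformity",
    "RunLengthNonuniformity",
    "RunPercentage",
)
_GLSZM_NAMES = (
    "HighIntensityEmphasis",
    "LowIntensityEmphasis",
    "LargeAreaEmphasis",
    "SmallAreaEmphasis",
    "IntensityVariability",
    "RunLengthVariability",
    "ZonePercentage",
)
_GLCM_3D_NAMES = (
    "Uniformity",
    "Entropy",
    "Dissimilarity",
    "Contrast",
    "Homogeneity",
    "Correlation",
)
_GLCM_2D_NAMES = (
    "Uniformity",
    "Entropy",
    "Dissimilarity",
    "Contrast",
    "Homogeneity",
    "InverseDifferenceMoment",
    "Correlation",
)
_NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")
_HIST_NAMES = ("Variance", "Entropy")


def _texture_feature_names() -> tuple[str, ...]:
    names: list[str] = []
    for n in _GLRLM_NAMES:
        names += [f"GLRLM_{n}_mean", f"GLRLM_{n}_max"]
    names += [f"GLSZM_{n}" for n in _GLSZM_NAMES]
    for n in _GLCM_3D_NAMES:
        names += [f"NGLCM3D_{n}_mean", f"NGLCM3D_{n}_max"]
    names += [f"NGLCM3DMean_{n}" for n in _GLCM_3D_NAMES]
    for n in _GLCM_2D_NAMES:
        names += [f"NGLCM_{n}_mean", f"NGLCM_{n}_max"]
    names += [f"NGTDM_{n}" for n in _NGTDM_NAMES]
    names += [f"SUVHistogram_{n}" for n in _HIST_NAMES]
    return tuple(names)


#: The 56 texture parameter names, in canonical column order.
TEXTURE_FEATURE_NAMES = _texture_feature_names()
assert len(TEXTURE_FEATURE_NAMES) == 56

#: 5 conventional + 56 texture parameter names.
ALL_FEATURE_NAMES = CONVENTIONAL_NAMES + TEXTURE_FEATURE_NAMES


@dataclass(frozen=True)
class ExtractionConfig:
    """Knobs of the feature-extraction stage."""

    n_levels: int = 64
    p_lo: float = 1.0
    p_hi: float = 99.0


# ---------------------------------------------------------------------------
# co-occurrence
# ---------------------------------------------------------------------------


@dataclass
class CooccurrenceMatrix:
    """Symmetric, normalized gray-level co-occurrence matrix at distance 1."""

    probs: np.ndarray
    direction: tuple[int, int, int]

    def __post_init__(self) -> None:
        s = self.probs.sum()
        if not np.isclose(s, 1.0, atol=1e-12):
            raise ValueError(f"co-occurrence probabilities must sum to 1, got {s}")
        if not np.allclose(self.probs, self.probs.T):
            raise ValueError("co-occurrence matrix must be symmetric")


def _offset_pairs(levels: np.ndarray, offset) -> tuple[np.ndarray, np.ndarray]:
    """Gray levels of all ordered in-mask voxel pairs (v, v + offset)."""
    sl_a, sl_b = [], []
    for o, n in zip(offset, levels.shape):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    a = levels[tuple(sl_a)]
    b = levels[tuple(sl_b)]
    valid = (a > 0) & (b > 0)
    return a[valid], b[valid]


def compute_glcm(
    dvoi: DiscretizedVoi, mode: str = "full3d"
) -> dict[tuple[int, int, int], CooccurrenceMatrix]:
    """Build co-occurrence matrices for ``slice2d`` (4 in-plane offsets,
    pairs pooled across slices) or ``full3d`` (13 offsets).

    Directions with no valid voxel pair are dropped with a warning; if every
    direction is dropped an error is raised.
    """
    if mode == "slice2d":
        offsets = DIRECTIONS_2D
    elif mode == "full3d":
        offsets = DIRECTIONS_3D
    else:
        raise ValueError(f"mode must be 'slice2d' or 'full3d', got {mode!r}")
    n = dvoi.n_levels
    out: dict[tuple[int, int, int], CooccurrenceMatrix] = {}
    for off in offsets:
        i, j = _offset_pairs(dvoi.levels, off)
        if i.size == 0:
            logger.warning("no co-occurrence pairs in direction %s; dropped", off)
            continue
        counts = np.bincount(
            (i.astype(np.int64) - 1) * n + (j.astype(np.int64) - 1),
            minlength=n * n,
        ).reshape(n, n).astype(float)
        counts = counts + counts.T  # symmetric accumulation of (i,j) and (j,i)
        out[off] = CooccurrenceMatrix(probs=counts / counts.sum(), direction=off)
    if not out:
        raise ValueError("no co-occurrence pairs in any direction")
    return out


def glcm_features(m: CooccurrenceMatrix) -> dict[str, float]:
    """Haralick-style features of one co-occurrence matrix.

    Correlation is defined as 0 when either marginal is degenerate.
    """
    p = m.probs
    n = p.shape[0]
    idx = np.arange(1, n + 1, dtype=float)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    absdiff = np.abs(ii - jj)

    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())

    px = p.sum(axis=1)
    mu_x = float((idx * px).sum())
    sig_x = float(np.sqrt((px * (idx - mu_x) ** 2).sum()))
    py = p.sum(axis=0)
    mu_y = float((idx * py).sum())
    sig_y = float(np.sqrt((py * (idx - mu_y) ** 2).sum()))
    if sig_x * sig_y == 0:
        correlation = 0.0
    else:
        correlation = float(((p * ii * jj).sum() - mu_x * mu_y) / (sig_x * sig_y))

    return {
        "Uniformity": float((p**2).sum()),
        "Entropy": entropy,
        "Dissimilarity": float((p * absdiff).sum()),
        "Contrast": float((p * absdiff**2).sum()),
        "Homogeneity": float((p / (1.0 + absdiff)).sum()),
        "InverseDifferenceMoment": float((p / (1.0 + absdiff**2)).sum()),
        "Correlation": correlation,
    }


def aggregate_directions(values) -> tuple[float, float]:
    """Arithmetic mean and max of per-direction feature values."""
    vals = list(values)
    if not vals:
        raise ValueError("no per-direction values to aggregate")
    return float(np.mean(vals)), float(np.max(vals))


def mean_cooccurrence_matrix(
    matrices: dict[tuple[int, int, int], CooccurrenceMatrix],
) -> CooccurrenceMatrix:
    """Element-wise average of co-occurrence matrices (still sums to 1)."""
    if not matrices:
        raise ValueError("no matrices to average")
    stack = np.stack([m.probs for m in matrices.values()])
    return CooccurrenceMatrix(probs=stack.mean(axis=0), direction=(0, 0, 0))


# ---------------------------------------------------------------------------
# run length
# ---------------------------------------------------------------------------


@dataclass
class RunLengthMatrix:
    """Counts of maximal same-level colinear runs, by level and length."""

    counts: np.ndarray  # (n_levels, max_run_length)
    direction: tuple[int, int, int]


def compute_glrlm(
    dvoi: DiscretizedVoi, directions=DIRECTIONS_3D
) -> dict[tuple[int, int, int], RunLengthMatrix]:
    """Run-length matrices along each direction (default: the 13 3D offsets).

    Runs are maximal sequences of equal-level in-mask voxels along the
    lattice line of the offset; every in-mask voxel belongs to exactly one
    run per direction, so ``sum_ij counts[i, j] * j`` equals the VOI voxel
    count in every direction.
    """
    if dvoi.n_voxels == 0:
        raise ValueError("empty VOI: no runs")
    lv = dvoi.levels
    coords = np.argwhere(lv > 0)
    levels = lv[tuple(coords.T)].astype(np.int64)
    out: dict[tuple[int, int, int], RunLengthMatrix] = {}
    for off in directions:
        d = np.asarray(off)
        ax = int(np.nonzero(d)[0][0])
        step = int(d[ax])
        # parametrize each lattice line p = p0 + t*d by t; p0 has component 0
        # on axis `ax`, so `base` is a unique per-line key.
        t = coords[:, ax] * step
        base = coords - t[:, None] * d[None, :]
        order = np.lexsort((t, base[:, 2], base[:, 1], base[:, 0]))
        t_s, base_s, lev_s = t[order], base[order], levels[order]
        if len(t_s) == 1:
            new_run = np.array([], dtype=bool)
        else:
            new_line = np.any(np.diff(base_s, axis=0) != 0, axis=1) | (
                np.diff(t_s) != 1
            )
            new_run = new_line | (np.diff(lev_s) != 0)
        starts = np.flatnonzero(np.concatenate(([True], new_run)))
        lengths = np.diff(np.concatenate((starts, [len(t_s)])))
        run_levels = lev_s[starts]
        max_len = int(lengths.max())
        counts = np.bincount(
            (run_levels - 1) * max_len + (lengths - 1),
            minlength=dvoi.n_levels * max_len,
        ).reshape(dvoi.n_levels, max_len)
        out[off] = RunLengthMatrix(counts=counts, direction=off)
    return out


def glrlm_features(m: RunLengthMatrix, n_voxels: int) -> dict[str, float]:
    r = m.counts.astype(float)
    n_runs = r.sum()
    j = np.arange(1, r.shape[1] + 1, dtype=float)
    return {
        "ShortRunsEmphasis": float((r / j**2).sum() / n_runs),
        "LongRunsEmphasis": float((r * j**2).sum() / n_runs),
        "GrayLevelNonuniformity": float((r.sum(axis=1) ** 2).sum() / n_runs),
        "RunLengthNonuniformity": float((r.sum(axis=0) ** 2).sum() / n_runs),
        "RunPercentage": float(n_runs / n_voxels),
    }


# ---------------------------------------------------------------------------
# size zone
# ---------------------------------------------------------------------------


@dataclass
class SizeZoneMatrix:
    """Counts of 26-connected equal-level zones, by level and zone size."""

    counts: np.ndarray  # (n_levels, max_zone_size)


def compute_glszm(dvoi: DiscretizedVoi) -> SizeZoneMatrix:
    """Size-zone matrix: zones are 26-connected components of equal level."""
    if dvoi.n_voxels == 0:
        raise ValueError("empty VOI: no zones")
    structure = np.ones((3, 3, 3), dtype=bool)
    zones: list[tuple[int, int]] = []
    for g in np.unique(dvoi.in_mask_levels()):
        labels, n_lab = ndimage.label(dvoi.levels == g, structure=structure)
        if n_lab:
            sizes = np.bincount(labels.ravel())[1:]
            zones.extend((int(g), int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    counts = np.zeros((dvoi.n_levels, max_size), dtype=np.int64)
    for g, s in zones:
        counts[g - 1, s - 1] += 1
    return SizeZoneMatrix(counts=counts)


def glszm_features(m: SizeZoneMatrix, n_voxels: int) -> dict[str, float]:
    """Size-zone features.

    ``IntensityVariability`` is the gray-level variability and
    ``RunLengthVariability`` the zone-size variability (the naming follows
    the run-length analogy used by the reporting layout).
    """
    z = m.counts.astype(float)
    n_zones = z.sum()
    i = np.arange(1, z.shape[0] + 1, dtype=float)[:, None]
    s = np.arange(1, z.shape[1] + 1, dtype=float)[None, :]
    return {
        "HighIntensityEmphasis": float((z * i**2).sum() / n_zones),
        "LowIntensityEmphasis": float((z / i**2).sum() / n_zones),
        "LargeAreaEmphasis": float((z * s**2).sum() / n_zones),
        "SmallAreaEmphasis": float((z / s**2).sum() / n_zones),
        "IntensityVariability": float((z.sum(axis=1) ** 2).sum() / n_zones),
        "RunLengthVariability": float((z.sum(axis=0) ** 2).sum() / n_zones),
        "ZonePercentage": float(n_zones / n_voxels),
    }


# ---------------------------------------------------------------------------
# neighborhood gray-tone difference
# ---------------------------------------------------------------------------


@dataclass
class NgtdmComponents:
    """Per-level occupancy and summed neighborhood deviation.

    ``n_i`` counts contributing voxels of level ``i`` (those with at least
    one in-mask neighbor), ``p_i = n_i / N`` their fraction, and ``s_i`` the
    summed absolute difference between ``i`` and the mean level of each
    voxel's in-mask 26-neighborhood.
    """

    n_i: np.ndarray
    p_i: np.ndarray
    s_i: np.ndarray
    n_total: int


def compute_ngtdm(dvoi: DiscretizedVoi) -> NgtdmComponents:
    if dvoi.n_voxels == 0:
        raise ValueError("empty VOI")
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    in_mask = dvoi.levels > 0
    nbr_sum = ndimage.convolve(dvoi.levels.astype(float), kernel, mode="constant")
    nbr_cnt = ndimage.convolve(in_mask.astype(float), kernel, mode="constant")
    contributing = in_mask & (nbr_cnt > 0.5)
    if not contributing.any():
        raise ValueError("every VOI voxel is neighbor-less; NGTDM undefined")
    g = dvoi.levels[contributing].astype(np.int64)
    nbr_mean = nbr_sum[contributing] / nbr_cnt[contributing]
    n_total = g.size
    n_i = np.bincount(g - 1, minlength=dvoi.n_levels).astype(np.int64)
    s_i = np.zeros(dvoi.n_levels)
    np.add.at(s_i, g - 1, np.abs(g - nbr_mean))
    return NgtdmComponents(n_i=n_i, p_i=n_i / n_total, s_i=s_i, n_total=n_total)


def ngtdm_features(c: NgtdmComponents) -> dict[str, float]:
    """Amadasun-King texture features from NGTDM components.

    Degenerate rules: coarseness is capped at 1e6 (the value reached by a
    perfectly uniform VOI with eps = 1e-6); contrast is 0 with a single
    occupied level; busyness is 0 when its denominator vanishes.  The
    busyness denominator runs over unordered occupied level pairs; the
    complexity and complexity/strength numerators run over the full double
    sum (diagonal terms vanish).
    """
    occ = np.flatnonzero(c.p_i > 0)
    i_occ = (occ + 1).astype(float)
    p = c.p_i[occ]
    s = c.s_i[occ]
    n_g = len(occ)
    n_tot = float(c.n_total)

    ps = float((c.p_i * c.s_i).sum())
    coarseness = min(1.0 / (NGTDM_EPS + ps), NGTDM_COARSENESS_CAP)

    if n_g < 2:
        contrast = 0.0
    else:
        di = i_occ[:, None] - i_occ[None, :]
        pij = p[:, None] * p[None, :]
        contrast = float(
            (pij * di**2).sum() / (n_g * (n_g - 1)) * (c.s_i.sum() / n_tot)
        )

    ipi = i_occ * p
    denom = float(np.abs(ipi[:, None] - ipi[None, :])[np.triu_indices(n_g, k=1)].sum())
    busyness = ps / denom if denom > 0 else 0.0

    if n_g < 2:
        complexity = 0.0
        strength = 0.0
    else:
        di = np.abs(i_occ[:, None] - i_occ[None, :])
        psum = p[:, None] + p[None, :]
        pssum = (p * s)[:, None] + (p * s)[None, :]
        complexity = float((di * pssum / (n_tot * psum)).sum())
        strength = float((psum * di**2).sum() / (NGTDM_EPS + c.s_i.sum()))

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------


def histogram_features(dvoi: DiscretizedVoi) -> dict[str, float]:
    """Gray-level histogram variance and entropy over the in-mask levels."""
    g = dvoi.in_mask_levels().astype(float)
    if g.size == 0:
        raise ValueError("empty VOI")
    counts = np.bincount(g.astype(np.int64) - 1, minlength=dvoi.n_levels)
    p = counts / counts.sum()
    levels = np.arange(1, dvoi.n_levels + 1, dtype=float)
    mean = float((p * levels).sum())
    variance = float((p * (levels - mean) ** 2).sum())
    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    return {"Variance": variance, "Entropy": entropy}


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _bounding_box_dvoi(dvoi: DiscretizedVoi) -> DiscretizedVoi:
    """Crop to the mask bounding box (pure speed; features are unchanged)."""
    idx = np.argwhere(dvoi.mask.flags)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return DiscretizedVoi(
        levels=dvoi.levels[sl],
        mask=LesionMask(flags=dvoi.mask.flags[sl], spacing=dvoi.spacing),
        n_levels=dvoi.n_levels,
        spacing=dvoi.spacing,
    )


def extract_texture(dvoi: DiscretizedVoi) -> dict[str, float]:
    """Compute all 56 texture parameters of a discretized VOI."""
    dvoi = _bounding_box_dvoi(dvoi)
    out: dict[str, float] = {}

    rlms = compute_glrlm(dvoi)
    per_dir = [glrlm_features(m, dvoi.n_voxels) for m in rlms.values()]
    for name in _GLRLM_NAMES:
        mean, mx = aggregate_directions(f[name] for f in per_dir)
        out[f"GLRLM_{name}_mean"] = mean
        out[f"GLRLM_{name}_max"] = mx

    szm_feats = glszm_features(compute_glszm(dvoi), dvoi.n_voxels)
    for name in _GLSZM_NAMES:
        out[f"GLSZM_{name}"] = szm_feats[name]

    mats3d = compute_glcm(dvoi, mode="full3d")
    per_dir = [glcm_features(m) for m in mats3d.values()]
    for name in _GLCM_3D_NAMES:
        mean, mx = aggregate_directions(f[name] for f in per_dir)
        out[f"NGLCM3D_{name}_mean"] = mean
        out[f"NGLCM3D_{name}_max"] = mx

    mean_feats = glcm_features(mean_cooccurrence_matrix(mats3d))
    for name in _GLCM_3D_NAMES:
        out[f"NGLCM3DMean_{name}"] = mean_feats[name]

    mats2d = compute_glcm(dvoi, mode="slice2d")
    per_dir = [glcm_features(m) for m in mats2d.values()]
    for name in _GLCM_2D_NAMES:
        mean, mx = aggregate_directions(f[name] for f in per_dir)
        out[f"NGLCM_{name}_mean"] = mean
        out[f"NGLCM_{name}_max"] = mx

    ngtdm_feats = ngtdm_features(compute_ngtdm(dvoi))
    for name in _NGTDM_NAMES:
        out[f"NGTDM_{name}"] = ngtdm_feats[name]

    hist = histogram_features(dvoi)
    for name in _HIST_NAMES:
        out[f"SUVHistogram_{name}"] = hist[name]

    assert tuple(out) == TEXTURE_FEATURE_NAMES
    return out


def extract_all(
    volume: PetVolume,
    mask: LesionMask,
    config: ExtractionConfig = ExtractionConfig(),
) -> dict[str, float]:
    """Full per-lesion feature vector: 5 conventional + 56 texture values.

    Discretizes the VOI (percentile window, ``config.n_levels`` bins) and
    runs every matrix family; keys follow :data:`ALL_FEATURE_NAMES`.
    """
    conv = compute_conventional(volume, mask).as_dict()
    dvoi = discretize(
        volume, mask, n_levels=config.n_levels, p_lo=config.p_lo, p_hi=config.p_hi
    )
    out = dict(conv)
    out.update(extract_texture(dvoi))
    assert tuple(out) == ALL_FEATURE_NAMES
    return out
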