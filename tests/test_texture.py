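import numpy as np
import pytest

import oracles
from conftest import full_mask, make_dvoi, make_volume, random_dvoi
from pettex.discretization import discretize
from pettex.texture import (
    DIRECTIONS_2D,
    DIRECTIONS_3D,
    TEXTURE_FEATURE_NAMES,
    CooccurrenceMatrix,
    aggregate_directions,
    compute_glcm,
    compute_glrlm,
    compute_glszm,
    compute_ngtdm,
    extract_all,
    extract_texture,
    glcm_features,
    glrlm_features,
    glszm_features,
    histogram_features,
    mean_cooccurrence_matrix,
    ngtdm_features,
)


def checkerboard(n=4):
    """Single-slice n x n checkerboard of levels {1, 2}."""
    g = np.indices((n, n)).sum(axis=0) % 2 + 1
    return make_dvoi(g.astype(np.int32), n_levels=2)


def uniform_dvoi(shape=(4, 4, 2), n_levels=4):
    return make_dvoi(np.ones(shape, dtype=np.int32), n_levels=n_levels)


# -- co-occurrence -----------------------------------------------------------


def test_uniform_dvoi_concentrates_all_probability():
    for mats in (compute_glcm(uniform_dvoi(), "full3d"),
                 compute_glcm(uniform_dvoi(), "slice2d")):
        for m in mats.values():
            assert m.probs[0, 0] == pytest.approx(1.0)


def test_checkerboard_pairs_all_discordant():
    mats = compute_glcm(checkerboard(), "slice2d")
    m = mats[(0, 1, 0)]
    assert m.probs[0, 1] == pytest.approx(0.5)
    assert m.probs[1, 0] == pytest.approx(0.5)
    assert m.probs[0, 0] == m.probs[1, 1] == 0.0


def test_single_voxel_has_no_pairs():
    d = make_dvoi(np.array([[[1]]], dtype=np.int32), n_levels=2)
    with pytest.raises(ValueError, match="no co-occurrence pairs"):
        compute_glcm(d, "full3d")


def test_glcm_features_degenerate_matrix():
    probs = np.zeros((3, 3))
    probs[0, 0] = 1.0
    f = glcm_features(CooccurrenceMatrix(probs=probs, direction=(1, 0, 0)))
    assert f == {
        "Uniformity": 1.0, "Entropy": 0.0, "Dissimilarity": 0.0, "Contrast": 0.0,
        "Homogeneity": 1.0, "InverseDifferenceMoment": 1.0, "Correlation": 0.0,
    }


def test_glcm_features_checkerboard_matrix_closed_form():
    probs = np.array([[0.0, 0.5], [0.5, 0.0]])
    f = glcm_features(CooccurrenceMatrix(probs=probs, direction=(0, 1, 0)))
    assert f["Contrast"] == pytest.approx(1.0)
    assert f["Dissimilarity"] == pytest.approx(1.0)
    assert f["Homogeneity"] == pytest.approx(0.5)
    assert f["InverseDifferenceMoment"] == pytest.approx(0.5)
    assert f["Uniformity"] == pytest.approx(0.5)
    assert f["Entropy"] == pytest.approx(1.0)
    assert f["Correlation"] == pytest.approx(-1.0)


def test_aggregate_directions():
    assert aggregate_directions([2.0, 2.0, 2.0]) == (2.0, 2.0)
    assert aggregate_directions([1.0, 3.0]) == (2.0, 3.0)
    with pytest.raises(ValueError):
        aggregate_directions([])


def test_mean_matrix_still_normalized():
    rng = np.random.default_rng(0)
    d = random_dvoi(rng, max_shape=(6, 6, 4), max_levels=6)
    mean = mean_cooccurrence_matrix(compute_glcm(d, "full3d"))
    assert mean.probs.sum() == pytest.approx(1.0, abs=1e-12)


# -- run length --------------------------------------------------------------


def test_uniform_rows_single_runs():
    d = make_dvoi(np.ones((4, 4), dtype=np.int32), n_levels=1)
    m = compute_glrlm(d, directions=[(0, 1, 0)])[(0, 1, 0)]
    f = glrlm_features(m, d.n_voxels)
    assert f["ShortRunsEmphasis"] == pytest.approx(1 / 16)
    assert f["LongRunsEmphasis"] == pytest.approx(16.0)
    assert f["GrayLevelNonuniformity"] == pytest.approx(4.0)
    assert f["RunLengthNonuniformity"] == pytest.approx(4.0)
    assert f["RunPercentage"] == pytest.approx(0.25)


def test_checkerboard_all_unit_runs():
    d = checkerboard()
    m = compute_glrlm(d, directions=[(0, 1, 0)])[(0, 1, 0)]
    f = glrlm_features(m, d.n_voxels)
    assert f["ShortRunsEmphasis"] == pytest.approx(1.0)
    assert f["LongRunsEmphasis"] == pytest.approx(1.0)
    assert f["RunPercentage"] == pytest.approx(1.0)
    assert f["GrayLevelNonuniformity"] == pytest.approx(8.0)
    assert f["RunLengthNonuniformity"] == pytest.approx(16.0)


def test_run_coverage_identity():
    """Every in-mask voxel lies in exactly one run per direction."""
    rng = np.random.default_rng(4)
    d = random_dvoi(rng)
    for m in compute_glrlm(d).values():
        j = np.arange(1, m.counts.shape[1] + 1)
        assert (m.counts * j).sum() == d.n_voxels


# -- size zone ---------------------------------------------------------------


def test_uniform_single_zone():
    d = make_dvoi(np.ones((4, 4), dtype=np.int32), n_levels=1)
    f = glszm_features(compute_glszm(d), d.n_voxels)
    assert f["SmallAreaEmphasis"] == pytest.approx(1 / 256)
    assert f["LargeAreaEmphasis"] == pytest.approx(256.0)
    assert f["ZonePercentage"] == pytest.approx(1 / 16)
    assert f["IntensityVariability"] == pytest.approx(1.0)
    assert f["RunLengthVariability"] == pytest.approx(1.0)


def test_checkerboard_diagonal_connectivity_merges_zones():
    # 26-connectivity joins diagonals: each level is ONE zone of 8 voxels
    d = checkerboard()
    f = glszm_features(compute_glszm(d), d.n_voxels)
    assert f["ZonePercentage"] == pytest.approx(2 / 16)
    assert f["LargeAreaEmphasis"] == pytest.approx(64.0)


def test_zone_size_identity():
    rng = np.random.default_rng(6)
    d = random_dvoi(rng)
    m = compute_glszm(d)
    s = np.arange(1, m.counts.shape[1] + 1)
    assert (m.counts * s).sum() == d.n_voxels


# -- NGTDM -------------------------------------------------------------------


def test_uniform_ngtdm_degenerate_values():
    f = ngtdm_features(compute_ngtdm(uniform_dvoi()))
    assert f["Coarseness"] == pytest.approx(1e6)
    assert f["Contrast"] == 0.0
    assert f["Busyness"] == 0.0
    assert f["Complexity"] == 0.0
    assert f["Strength"] == 0.0


def test_ngtdm_cross_pattern_matches_oracle():
    levels = np.array([[1, 2, 1], [2, 3, 2], [1, 2, 1]], dtype=np.int32)
    d = make_dvoi(levels, n_levels=3)
    f = ngtdm_features(compute_ngtdm(d))
    n_i, s_i, total = oracles.ngtdm_bruteforce(d.levels, 3)
    expected = oracles.ngtdm_features_bruteforce(n_i, s_i, total)
    for name, v in expected.items():
        assert f[name] == pytest.approx(v, abs=1e-10), name


def test_interleaved_levels_busyness_finite():
    d = checkerboard()
    f = ngtdm_features(compute_ngtdm(d))
    assert np.isfinite(f["Busyness"]) and f["Busyness"] > 0


# -- histogram ---------------------------------------------------------------


def test_histogram_uniform_and_bimodal():
    assert histogram_features(uniform_dvoi()) == {"Variance": 0.0, "Entropy": 0.0}
    levels = np.concatenate([np.full(32, 1), np.full(32, 64)]).astype(np.int32)
    d = make_dvoi(levels.reshape(8, 8), n_levels=64)
    f = histogram_features(d)
    assert f["Variance"] == pytest.approx(992.25)
    assert f["Entropy"] == pytest.approx(1.0)


# -- randomized oracle spot-check (the full sweep lives in acceptance) -------


def test_random_dvois_match_bruteforce_oracles():
    rng = np.random.default_rng(123)
    for _ in range(15):
        d = random_dvoi(rng)
        lv, n = d.levels, d.n_levels
        for off, m in compute_glcm(d, "full3d").items():
            c = oracles.glcm_counts_bruteforce(lv, off, n)
            np.testing.assert_allclose(m.probs, c / c.sum(), atol=1e-12)
            expected = oracles.glcm_features_bruteforce(m.probs)
            got = glcm_features(m)
            for k, v in expected.items():
                assert got[k] == pytest.approx(v, abs=1e-10), k
        for off, m in compute_glrlm(d).items():
            runs = oracles.glrlm_bruteforce(lv, off, n)
            expected = oracles.glrlm_features_bruteforce(runs, d.n_voxels)
            got = glrlm_features(m, d.n_voxels)
            for k, v in expected.items():
                assert got[k] == pytest.approx(v, abs=1e-10), k


# -- whole-VOI invariants ----------------------------------------------------


def test_extract_texture_has_exactly_56_finite_values():
    rng = np.random.default_rng(77)
    feats = extract_texture(random_dvoi(rng, max_shape=(8, 8, 5), max_levels=8))
    assert tuple(feats) == TEXTURE_FEATURE_NAMES
    assert len(feats) == 56
    assert all(np.isfinite(v) for v in feats.values())


def test_uniform_voi_limiting_feature_values():
    rng_vals = np.full((6, 6, 4), 2.5)
    vol = make_volume(rng_vals)
    feats = extract_all(vol, full_mask(vol))
    for name, v in feats.items():
        base = name.split("_")[1] if "_" in name else name
        if base in ("Entropy", "Dissimilarity", "Contrast"):
            assert v == 0.0, name
        if base in ("Homogeneity", "InverseDifferenceMoment"):
            assert v == pytest.approx(1.0), name
    assert feats["NGTDM_Busyness"] == 0.0
    assert feats["NGTDM_Complexity"] == 0.0
    assert feats["NGTDM_Strength"] == 0.0
    assert feats["SUVHistogram_Variance"] == 0.0


def test_mirroring_preserves_mean_aggregated_features():
    rng = np.random.default_rng(8)
    d = random_dvoi(rng, max_shape=(6, 6, 4), max_levels=6)
    base = extract_texture(d)
    for axis in range(3):
        mirrored = make_dvoi(np.flip(d.levels, axis=axis).copy(), d.n_levels)
        flipped = extract_texture(mirrored)
        for name in TEXTURE_FEATURE_NAMES:
            if name.endswith("_mean") or not name.endswith("_max"):
                assert flipped[name] == pytest.approx(base[name], abs=1e-9), name


def test_checkerboard_strictly_more_heterogeneous_than_uniform():
    uni = extract_texture(make_dvoi(np.ones((6, 6), dtype=np.int32) * 1, 2))
    chk = extract_texture(checkerboard(6))
    assert chk["NGLCM_Contrast_mean"] > uni["NGLCM_Contrast_mean"]
    assert chk["NGTDM_Busyness"] > uni["NGTDM_Busyness"]
    assert chk["NGLCM_Homogeneity_mean"] < uni["NGLCM_Homogeneity_mean"]


def test_texture_invariant_to_affine_suv_rescale():
    rng = np.random.default_rng(10)
    vals = rng.uniform(1, 8, (7, 7, 5))
    vol = make_volume(vals)
    scaled = make_volume(2.7 * vals + 1.3)
    mask = full_mask(vol)
    f1 = extract_all(vol, mask)
    f2 = extract_all(scaled, mask)
    for name in TEXTURE_FEATURE_NAMES:
        assert f1[name] == f2[name], name
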