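"""Discretization, texture matrices and the default feature vector."""

import numpy as np
import pytest

from conftest import roi_from_bins
from radpipe import (
    ExtractionSettings,
    PhantomSpec,
    Sphere,
    extract_cohort,
    extract_features,
    generate_phantom,
)
from radpipe.features import (
    DIRECTIONS_13,
    FEATURE_COUNTS,
    compute_feature_class,
    compute_texture_matrix,
    feature_names,
    glcm_matrices,
    glrlm_matrices,
)
from radpipe.features.discretize import discretize_array
from radpipe.image_io import ImageVolume, SegmentationMask


# ----------------------------------------------------------- discretize


def test_discretize_floor_formula():
    """values {0, 63.9, 64, 130} at width 64 -> bins {1, 1, 2, 3}."""
    values = np.array([[[0.0, 63.9, 64.0, 130.0]]])
    roi = discretize_array(values, np.ones_like(values, bool), 64.0)
    np.testing.assert_array_equal(roi.masked_bins, [1, 1, 2, 3])
    assert roi.n_levels == 3


def test_discretize_constant_roi():
    values = np.full((1, 2, 2), 42.0)
    roi = discretize_array(values, np.ones_like(values, bool), 64.0)
    assert roi.n_levels == 1
    assert set(roi.masked_bins.tolist()) == {1}


def test_discretize_shift_invariance():
    rng = np.random.default_rng(0)
    values = rng.uniform(-500, 500, size=(3, 4, 4))
    mask = rng.random((3, 4, 4)) > 0.3
    a = discretize_array(values, mask, 25.0)
    b = discretize_array(values + 500.0, mask, 25.0)
    np.testing.assert_array_equal(a.bins, b.bins)


def test_discretize_rejects_bad_width():
    values = np.ones((1, 2, 2))
    with pytest.raises(ValueError, match="bin_width"):
        discretize_array(values, np.ones_like(values, bool), 0.0)


# ------------------------------------------------------ texture matrices


def test_glcm_1d_pair_counts():
    """[1,1,2,2] with offset +1: symmetric counts {(1,1):2,(1,2):2,(2,2):2}."""
    roi = roi_from_bins(np.array([[[1, 1, 2, 2]]]))
    mats = glcm_matrices(roi)
    nonzero = [m for m in mats if m.sum() > 0]
    assert len(nonzero) == 1  # only the in-row direction has pairs
    m = nonzero[0]
    # normalized from raw symmetric counts 2/2/2 (total 6)
    np.testing.assert_allclose(
        m, np.array([[2, 1], [1, 2]]) / 6.0, atol=1e-12
    )
    assert m.sum() == pytest.approx(1.0)


def test_glcm_constant_roi_single_cell():
    roi = roi_from_bins(np.ones((1, 2, 2), dtype=int))
    mats = glcm_matrices(roi)
    for m in mats:
        if m.sum() > 0:
            assert m.shape == (1, 1)
            assert m[0, 0] == pytest.approx(1.0)


def test_glrlm_horizontal_runs():
    """[[1,1],[2,2]]: horizontal runs {(1, len 2): 1, (2, len 2): 1}."""
    roi = roi_from_bins(np.array([[[1, 1], [2, 2]]]))
    mats = glrlm_matrices(roi)
    horizontal = mats[DIRECTIONS_13.index((0, 0, 1))]
    np.testing.assert_array_equal(horizontal, [[0, 1], [0, 1]])


def test_texture_matrix_dispatcher():
    roi = roi_from_bins(np.array([[[1, 2], [2, 1]]]))
    for family in ("glcm", "glrlm", "glszm", "gldm", "ngtdm"):
        tm = compute_texture_matrix(roi, family)
        assert tm.family == family.upper()
        assert np.all(tm.values >= 0)
    with pytest.raises(ValueError, match="unknown"):
        compute_texture_matrix(roi, "glxxx")


# ------------------------------------------------------- feature vector


def test_default_extraction_yields_107(sphere_phantom):
    volume, mask = sphere_phantom
    feats = extract_features(volume, mask)
    assert len(feats) == 107
    assert list(feats) == feature_names()
    assert all(np.isfinite(v) for v in feats.values())
    assert (
        "original_gldm_SmallDependenceHighGrayLevelEmphasis" in feats
    )


def test_class_counts_sum_to_107():
    assert sum(FEATURE_COUNTS.values()) == 107


def test_firstorder_only_yields_18(sphere_phantom):
    volume, mask = sphere_phantom
    feats = extract_features(
        volume, mask, ExtractionSettings(classes=("firstorder",))
    )
    assert len(feats) == 18


def test_firstorder_mean_and_voxel_volume():
    values = np.array([[[1.0, 2.0], [3.0, 4.0]]])
    vol = ImageVolume(values, (1, 1, 1), (0, 0, 0), (1, 0, 0, 0, 1, 0))
    mask = SegmentationMask(np.ones_like(values, bool))
    fo = compute_feature_class(vol, mask, "firstorder")
    assert fo["original_firstorder_Mean"] == pytest.approx(2.5)
    assert fo["original_firstorder_Minimum"] == 1.0
    assert fo["original_firstorder_Range"] == 3.0
    # 10x10x10 cube at 1 mm -> VoxelVolume 1000 mm^3
    cube = np.zeros((12, 12, 12))
    cube_mask = np.zeros_like(cube, bool)
    cube_mask[1:11, 1:11, 1:11] = True
    vol2 = ImageVolume(cube, (1, 1, 1), (0, 0, 0), (1, 0, 0, 0, 1, 0))
    sh = compute_feature_class(
        vol2, SegmentationMask(cube_mask), "shape"
    )
    assert sh["original_shape_VoxelVolume"] == pytest.approx(1000.0)


def test_shift_invariance_of_texture_features(sphere_phantom):
    """Adding a constant leaves all min-anchored features unchanged."""
    volume, mask = sphere_phantom
    shifted = ImageVolume(
        volume.voxels + 500.0, volume.spacing, volume.origin,
        volume.orientation,
    )
    location_dependent = {
        "original_firstorder_10Percentile",
        "original_firstorder_90Percentile",
        "original_firstorder_Energy",
        "original_firstorder_Maximum",
        "original_firstorder_Mean",
        "original_firstorder_Median",
        "original_firstorder_Minimum",
        "original_firstorder_RootMeanSquared",
        "original_firstorder_TotalEnergy",
    }
    a = extract_features(volume, mask)
    b = extract_features(shifted, mask)
    for name in a:
        if name not in location_dependent:
            assert a[name] == pytest.approx(b[name], rel=1e-9), name


def test_rotation_invariance_on_isotropic_phantom():
    """90-degree in-plane rotation permutes directions, so direction-
    aggregated features are unchanged."""
    volume, mask = generate_phantom(
        PhantomSpec(
            lesions=(Sphere((16, 15, 18), 5.0, 100.0),),
            noise_sd=40.0,
            seed=4,
        )
    )
    rot_vol = ImageVolume(
        np.rot90(volume.voxels, axes=(1, 2)).copy(),
        volume.spacing, volume.origin, volume.orientation,
    )
    rot_mask = SegmentationMask(np.rot90(mask.voxels, axes=(1, 2)).copy())
    settings = ExtractionSettings(
        classes=("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")
    )
    a = extract_features(volume, mask, settings)
    b = extract_features(rot_vol, rot_mask, settings)
    for name in a:
        assert a[name] == pytest.approx(b[name], rel=1e-9), name


def test_single_grey_level_roi_is_finite():
    values = np.full((2, 3, 3), 5.0)
    vol = ImageVolume(values, (1, 1, 1), (0, 0, 0), (1, 0, 0, 0, 1, 0))
    mask = SegmentationMask(np.ones_like(values, bool))
    with pytest.warns(UserWarning, match="single grey level"):
        feats = extract_features(vol, mask)
    assert all(np.isfinite(v) for v in feats.values())
    assert feats["original_glcm_Correlation"] == 0.0
    assert feats["original_firstorder_Entropy"] == 0.0


def test_empty_mask_rejected(sphere_phantom):
    volume, _ = sphere_phantom
    empty = SegmentationMask(np.zeros(volume.shape, bool))
    with pytest.raises(ValueError, match="empty"):
        extract_features(volume, empty)


# ------------------------------------------------------------- cohorts


def test_cohort_shape_and_determinism(tmp_path):
    studies = []
    for i in range(3):
        vol, mask = generate_phantom(PhantomSpec(noise_sd=20.0, seed=i))
        studies.append((vol, mask, f"P{i}", i % 2, 1))
    t1 = extract_cohort(studies, out_dir=tmp_path / "a")
    t2 = extract_cohort(studies, out_dir=tmp_path / "b")
    assert t1.shape == (3, 3 + 107)
    assert (tmp_path / "a" / "cohort.csv").read_bytes() == (
        tmp_path / "b" / "cohort.csv"
    ).read_bytes()


def test_cohort_duplicate_and_empty_errors(sphere_phantom):
    volume, mask = sphere_phantom
    with pytest.raises(ValueError, match="duplicate patient id"):
        extract_cohort(
            [(volume, mask, "P1", 0, 1), (volume, mask, "P1", 1, 1)]
        )
    empty = SegmentationMask(np.zeros(volume.shape, bool))
    with pytest.raises(ValueError, match="P9"):
        extract_cohort([(volume, empty, "P9", 0, 1)])
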