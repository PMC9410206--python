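"""DICOM import, mask import and overlap verification."""

import numpy as np
import pydicom
import pytest

from radpipe import (
    PhantomSpec,
    generate_phantom,
    load_dicom_series,
    load_mask,
    verify_overlap,
    write_dicom_series,
    write_mask,
)
from radpipe.image_io import DicomImportError, MaskAlignmentError, SegmentationMask


@pytest.fixture()
def series_dir(tmp_path, clean_phantom):
    volume, _ = clean_phantom
    write_dicom_series(volume, tmp_path / "series")
    return tmp_path / "series"


def test_round_trip_preserves_voxels_and_geometry(tmp_path):
    volume, _ = generate_phantom(PhantomSpec(noise_sd=25.0, seed=3))
    write_dicom_series(volume, tmp_path / "s")
    loaded = load_dicom_series(tmp_path / "s")
    np.testing.assert_array_equal(loaded.voxels, volume.voxels)
    assert loaded.spacing == pytest.approx(volume.spacing, abs=1e-6)
    assert loaded.origin == pytest.approx(volume.origin, abs=1e-6)
    assert loaded.modality == "CT"
    assert len(loaded.source_meta) == volume.shape[0]


def test_slice_order_is_permutation_invariant(tmp_path, clean_phantom):
    """Shuffled file names on disk must yield the identical volume."""
    volume, _ = clean_phantom
    write_dicom_series(volume, tmp_path / "s")
    paths = sorted((tmp_path / "s").iterdir())
    rng = np.random.default_rng(0)
    shuffled_dir = tmp_path / "shuffled"
    shuffled_dir.mkdir()
    for new_idx, path in zip(rng.permutation(len(paths)), paths):
        (shuffled_dir / f"file_{new_idx:04d}.dcm").write_bytes(path.read_bytes())
    a = load_dicom_series(tmp_path / "s")
    b = load_dicom_series(shuffled_dir)
    np.testing.assert_array_equal(a.voxels, b.voxels)
    assert a.origin == b.origin


def test_rescale_slope_intercept_applied(tmp_path, series_dir):
    """stored 600 with slope 2, intercept -1024 -> 176 HU."""
    path = sorted(series_dir.iterdir())[0]
    ds = pydicom.dcmread(path)
    arr = np.full((ds.Rows, ds.Columns), 600, dtype=np.uint16)
    ds.PixelData = arr.tobytes()
    ds.RescaleSlope = 2.0
    ds.RescaleIntercept = -1024.0
    solo = tmp_path / "solo"
    solo.mkdir()
    ds.save_as(solo / "slice.dcm", enforce_file_format=True)
    volume = load_dicom_series(solo)
    assert volume.voxels[0, 0, 0] == pytest.approx(176.0)


def test_mixed_series_uids_rejected(tmp_path, series_dir):
    other = pydicom.dcmread(sorted(series_dir.iterdir())[0])
    other.SeriesInstanceUID = pydicom.uid.generate_uid()
    other.ImagePositionPatient = [0.0, 0.0, 999.0]
    other.save_as(series_dir / "alien.dcm", enforce_file_format=True)
    with pytest.raises(DicomImportError, match="series UID"):
        load_dicom_series(series_dir)


def test_missing_geometry_tag_named(tmp_path, series_dir):
    path = sorted(series_dir.iterdir())[0]
    ds = pydicom.dcmread(path)
    del ds.ImagePositionPatient
    solo = tmp_path / "bad"
    solo.mkdir()
    ds.save_as(solo / "slice.dcm", enforce_file_format=True)
    with pytest.raises(DicomImportError, match="ImagePositionPatient"):
        load_dicom_series(solo)


def test_duplicate_slice_positions_rejected(tmp_path, series_dir):
    path = sorted(series_dir.iterdir())[0]
    dup = pydicom.dcmread(path)
    dup.SOPInstanceUID = pydicom.uid.generate_uid()
    dup.save_as(series_dir / "dup.dcm", enforce_file_format=True)
    with pytest.raises(DicomImportError, match="duplicate slice positions"):
        load_dicom_series(series_dir)


def test_mask_round_trip_and_binarization(tmp_path, clean_phantom):
    volume, mask = clean_phantom
    path = write_mask(mask, tmp_path / "mask.dcm")
    loaded = load_mask(path, volume)
    np.testing.assert_array_equal(loaded.voxels, mask.voxels)
    # values {0, 255} binarize to foreground where 255
    arr = np.zeros(volume.shape, dtype=np.uint8)
    arr[10:12, 10:12, 10:12] = 255
    npy = tmp_path / "m.npy"
    np.save(npy, arr)
    m = load_mask(npy, volume)
    assert m.voxel_count == 8


def test_mask_dimension_mismatch_rejected(tmp_path, clean_phantom):
    volume, _ = clean_phantom
    np.save(tmp_path / "bad.npy", np.ones((4, 4, 4), dtype=np.uint8))
    with pytest.raises(MaskAlignmentError, match="does not match"):
        load_mask(tmp_path / "bad.npy", volume)


def test_empty_mask_loads_with_flag(tmp_path, clean_phantom):
    volume, _ = clean_phantom
    np.save(tmp_path / "zero.npy", np.zeros(volume.shape, dtype=np.uint8))
    with pytest.warns(UserWarning, match="empty"):
        m = load_mask(tmp_path / "zero.npy", volume)
    assert m.is_empty


@pytest.mark.parametrize(
    "window,where,expected",
    [
        ((50, 150), "lesion", True),   # lesion value 100 inside window
        ((50, 150), "background", False),  # mask on -1000 background
    ],
)
def test_verify_overlap_window(clean_phantom, window, where, expected):
    volume, mask = clean_phantom
    if where == "background":
        shifted = np.zeros_like(mask.voxels)
        shifted[1:4, 1:4, 1:4] = True  # far from the lesion
        mask = SegmentationMask(shifted, parent_shape=volume.shape)
    ok, report = verify_overlap(mask, volume, window)
    assert ok is expected
    assert report["foreground_voxels"] > 0


def test_verify_overlap_empty_mask_false(clean_phantom):
    volume, _ = clean_phantom
    empty = SegmentationMask(
        np.zeros(volume.shape, dtype=bool), parent_shape=volume.shape
    )
    ok, report = verify_overlap(empty, volume, (50, 150))
    assert ok is False
    assert report["foreground_voxels"] == 0
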