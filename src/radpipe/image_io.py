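"""DICOM series import and segmentation-mask handling.

A scan is represented as an :class:`ImageVolume`: a 3D scalar grid in
physical units (Hounsfield units for CT, native units otherwise) together
with its geometry (voxel spacing, origin, direction cosines).  Slices are
always sorted along the scan normal — the projection of each slice's
``ImagePositionPatient`` onto the cross product of the row and column
direction cosines — which is robust against unreliable instance numbers
and arbitrary on-disk file order.

Segmentations are accepted as raster volumes aligned to the parent scan:
either a directory of single-frame DICOM files, a single multi-frame DICOM
file, or a NumPy ``.npy`` binary grid.  Contour formats (DICOM-RT) are out
of scope; masks must already be rasterized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

__all__ = [
    "ImageVolume",
    "SegmentationMask",
    "DicomImportError",
    "MaskAlignmentError",
    "load_dicom_series",
    "write_dicom_series",
    "load_mask",
    "write_mask",
    "verify_overlap",
]

_REQUIRED_GEOMETRY_TAGS = (
    "ImagePositionPatient",
    "ImageOrientationPatient",
    "PixelSpacing",
    "Rows",
    "Columns",
)

_POSITION_TOL_MM = 1e-6


class DicomImportError(ValueError):
    """A DICOM directory cannot be assembled into a consistent volume."""


class MaskAlignmentError(ValueError):
    """A segmentation does not align with its reference volume."""


@dataclass
class ImageVolume:
    """A 3D scalar image with geometry metadata.

    Attributes
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        Intensities after rescale slope/intercept, i.e. HU for CT.
    spacing : tuple of float
        (row, column, slice) spacing in mm; all strictly positive.
    origin : tuple of float
        Physical position (x, y, z) of the first voxel, in mm.
    orientation : tuple of float
        Six direction cosines (row direction, then column direction).
    modality : str
        DICOM modality, e.g. "CT", "PT", "MR".
    source_meta : list of dict
        Per-slice record (position, slope/intercept, scanner model, ...).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    orientation: tuple[float, ...]
    modality: str = "CT"
    source_meta: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array (slice, row, column)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacings must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def axis_spacing(self) -> tuple[float, float, float]:
        """Spacing ordered like the voxel axes: (slice, row, column)."""
        r, c, s = self.spacing
        return (s, r, c)

    @property
    def slice_normal(self) -> np.ndarray:
        row = np.asarray(self.orientation[:3], dtype=float)
        col = np.asarray(self.orientation[3:6], dtype=float)
        return np.cross(row, col)


@dataclass
class SegmentationMask:
    """A binary 3D grid geometrically aligned to an :class:`ImageVolume`."""

    voxels: np.ndarray
    label_name: str = "lesion"
    parent_shape: tuple[int, int, int] | None = None
    parent_spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels) > 0
        if self.voxels.ndim != 3:
            raise ValueError("mask must be a 3D array (slice, row, column)")
        if self.parent_shape is not None and tuple(self.voxels.shape) != tuple(
            self.parent_shape
        ):
            raise MaskAlignmentError(
                f"mask shape {self.voxels.shape} does not match reference "
                f"shape {tuple(self.parent_shape)}"
            )

    @property
    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    def check_aligned(self, volume: ImageVolume) -> None:
        if self.voxels.shape != volume.shape:
            raise MaskAlignmentError(
                f"mask shape {self.voxels.shape} does not match volume "
                f"shape {volume.shape}"
            )


def _read_series_datasets(directory_path: str | Path) -> list[pydicom.Dataset]:
    directory = Path(directory_path)
    if not directory.is_dir():
        raise DicomImportError(f"not a directory: {directory}")
    datasets = []
    for path in sorted(directory.iterdir()):
        if path.is_dir():
            continue
        try:
            ds = pydicom.dcmread(str(path))
        except Exception as exc:  # non-DICOM files are a hard error
            raise DicomImportError(f"cannot read {path.name} as DICOM: {exc}")
        datasets.append(ds)
    if not datasets:
        raise DicomImportError(f"no DICOM files found in {directory}")
    return datasets


def load_dicom_series(directory_path: str | Path) -> ImageVolume:
    """Assemble a directory of single-frame DICOM files into a volume.

    Slices are sorted by the projection of ``ImagePositionPatient`` onto
    the slice normal; stored values are converted to physical units with
    ``value = stored * RescaleSlope + RescaleIntercept``.

    Raises
    ------
    DicomImportError
        On mixed series UIDs, inconsistent in-plane dimensions, missing
        geometry tags (named in the message), or duplicate slice positions.
    """
    datasets = _read_series_datasets(directory_path)

    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(uids) > 1:
        raise DicomImportError(
            f"directory mixes {len(uids)} different series UIDs"
        )

    for ds in datasets:
        for tag in _REQUIRED_GEOMETRY_TAGS:
            if getattr(ds, tag, None) is None:
                raise DicomImportError(f"missing required DICOM tag: {tag}")

    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) > 1:
        raise DicomImportError(
            f"inconsistent in-plane dimensions across slices: {sorted(shapes)}"
        )

    first = datasets[0]
    orientation = tuple(float(v) for v in first.ImageOrientationPatient)
    row = np.array(orientation[:3])
    col = np.array(orientation[3:6])
    normal = np.cross(row, col)

    projections = np.array(
        [float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal)) for ds in datasets]
    )
    order = np.argsort(projections, kind="stable")
    sorted_proj = projections[order]
    if len(datasets) > 1:
        gaps = np.diff(sorted_proj)
        if np.any(gaps < _POSITION_TOL_MM):
            raise DicomImportError(
                "duplicate slice positions along the scan normal"
            )
        slice_spacing = float(np.median(gaps))
    else:
        slice_spacing = float(getattr(first, "SliceThickness", 1.0) or 1.0)

    slices = []
    source_meta = []
    for idx in order:
        ds = datasets[idx]
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
        source_meta.append(
            {
                "slice_location": float(getattr(ds, "SliceLocation", np.dot(
                    np.asarray(ds.ImagePositionPatient, float), normal))),
                "rescale_slope": slope,
                "rescale_intercept": intercept,
                "manufacturer_model_name": str(
                    getattr(ds, "ManufacturerModelName", "")
                ),
                "instance_number": int(getattr(ds, "InstanceNumber", 0) or 0),
                "position": [float(v) for v in ds.ImagePositionPatient],
            }
        )

    pixel_spacing = [float(v) for v in first.PixelSpacing]
    origin_ds = datasets[order[0]]
    return ImageVolume(
        voxels=np.stack(slices, axis=0),
        spacing=(pixel_spacing[0], pixel_spacing[1], slice_spacing),
        origin=tuple(float(v) for v in origin_ds.ImagePositionPatient),
        orientation=orientation,
        modality=str(getattr(first, "Modality", "CT")),
        source_meta=source_meta,
    )


def _base_dataset(modality: str, series_uid: str) -> FileDataset:
    meta = Dataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = modality
    ds.SeriesInstanceUID = series_uid
    ds.StudyInstanceUID = series_uid  # single-study export
    ds.PatientName = "phantom"
    ds.PatientID = "phantom"
    return ds


def write_dicom_series(volume: ImageVolume, directory_path: str | Path) -> list[Path]:
    """Write a volume as a series of single-frame DICOM files.

    Intensities are stored as unsigned 16-bit values with a rescale
    intercept of −1024 (CT convention), so voxel values must be integral
    and lie in [−1024, 64511].  Round-trips through
    :func:`load_dicom_series` reproduce voxel values exactly.
    """
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    intercept = -1024.0
    stored = np.round(volume.voxels - intercept)
    if np.any(stored < 0) or np.any(stored > 65535):
        raise ValueError("voxel values out of storable range [-1024, 64511]")
    if not np.allclose(stored, volume.voxels - intercept, atol=1e-9):
        raise ValueError("voxel values must be integral for DICOM export")

    row_sp, col_sp, slice_sp = volume.spacing
    series_uid = generate_uid()
    paths = []
    n_slices = volume.shape[0]
    normal = volume.slice_normal
    origin = np.asarray(volume.origin, dtype=float)
    for k in range(n_slices):
        ds = _base_dataset(volume.modality, series_uid)
        ds.Rows, ds.Columns = volume.shape[1], volume.shape[2]
        ds.PixelSpacing = [row_sp, col_sp]
        ds.SliceThickness = slice_sp
        ds.ImageOrientationPatient = list(volume.orientation)
        position = origin + k * slice_sp * normal
        ds.ImagePositionPatient = [float(v) for v in position]
        ds.SliceLocation = float(np.dot(position, normal))
        ds.InstanceNumber = k + 1
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = intercept
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = stored[k].astype(np.uint16).tobytes()
        path = directory / f"slice_{k:04d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths


def _load_mask_array(path: Path, reference: ImageVolume) -> np.ndarray:
    if path.is_dir():
        return load_dicom_series(path).voxels
    if path.suffix == ".npy":
        return np.load(str(path))
    ds = pydicom.dcmread(str(path))
    n_frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
    arr = ds.pixel_array
    if n_frames == 1 and arr.ndim == 2:
        arr = arr[np.newaxis]
    return np.asarray(arr)


def load_mask(path: str | Path, reference: ImageVolume, label_name: str | None = None) -> SegmentationMask:
    """Import a raster segmentation aligned to ``reference``.

    Accepts a directory of single-frame DICOM files, a single multi-frame
    DICOM file, or a ``.npy`` binary grid.  Any value > 0 maps to
    foreground.  An all-zero mask loads but is flagged empty.
    """
    path = Path(path)
    arr = _load_mask_array(path, reference)
    if arr.shape != reference.shape:
        raise MaskAlignmentError(
            f"mask shape {tuple(arr.shape)} does not match reference shape "
            f"{reference.shape}"
        )
    mask = SegmentationMask(
        voxels=arr > 0,
        label_name=label_name or path.stem,
        parent_shape=reference.shape,
        parent_spacing=reference.spacing,
    )
    if mask.is_empty:
        warnings.warn(
            f"mask {mask.label_name!r} is empty and unusable for extraction",
            stacklevel=2,
        )
    return mask


def write_mask(mask: SegmentationMask, path: str | Path) -> Path:
    """Export a mask as a multi-frame DICOM raster volume."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds = _base_dataset("OT", generate_uid())
    data = mask.voxels.astype(np.uint8)
    ds.NumberOfFrames = data.shape[0]
    ds.Rows, ds.Columns = data.shape[1], data.shape[2]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelData = data.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return path


def verify_overlap(
    mask: SegmentationMask,
    volume: ImageVolume,
    intensity_window: tuple[float, float],
) -> tuple[bool, dict]:
    """Check that a mask actually covers the intended target.

    The masked intensity statistics must fall inside ``intensity_window``
    (a plausible target range, e.g. soft-tissue HU for a lung nodule); a
    mask sitting on background fails the check, as does an empty mask.

    Returns ``(ok, report)`` where the report carries the masked min /
    mean / max and the foreground voxel count.
    """
    mask.check_aligned(volume)
    lo, hi = intensity_window
    if mask.is_empty:
        return False, {
            "foreground_voxels": 0,
            "min": None,
            "mean": None,
            "max": None,
            "window": [lo, hi],
        }
    values = volume.voxels[mask.voxels]
    report = {
        "foreground_voxels": int(values.size),
        "min": float(values.min()),
        "mean": float(values.mean()),
        "max": float(values.max()),
        "window": [lo, hi],
    }
    ok = lo <= report["min"] and report["max"] <= hi
    return bool(ok), report
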