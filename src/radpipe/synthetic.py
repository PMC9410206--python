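"""Synthetic phantoms and feature tables with known ground truth.

Every downstream stage of the pipeline is testable without any image
download:

* :func:`generate_phantom` builds small 3D CT-like volumes (background
  −1000 HU, like air in a lung window) with embedded lesions of known
  intensity (spheres or boxes) plus the exact foreground mask, and can
  write them through the public DICOM writer so fixtures enter via the
  same readers users employ.
* :func:`generate_feature_table` emulates a multi-scanner cohort: i.i.d.
  Gaussian features, a stated class effect on a chosen subset, and
  per-batch additive/multiplicative distortions.  The default spec
  mirrors a two-class lung-nodule cohort: 28 vs 63 patients spread over
  five scanner batches sized (19, 50, 13, 5, 4).

All generators are pure functions of their spec (seed included); noise
is rounded to integer HU so DICOM round trips are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .image_io import ImageVolume, SegmentationMask, write_dicom_series, write_mask

__all__ = [
    "Sphere",
    "Box",
    "PhantomSpec",
    "TableSpec",
    "generate_phantom",
    "write_phantom_dicom",
    "generate_feature_table",
    "DEFAULT_TABLE_SPEC",
]


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]  # voxel indices (slice, row, col)
    radius: float
    intensity: float = 100.0


@dataclass(frozen=True)
class Box:
    lower: tuple[int, int, int]
    upper: tuple[int, int, int]
    intensity: float = 100.0


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (row, col, slice) mm
    background: float = -1000.0
    lesions: tuple = (Sphere(center=(16, 16, 16), radius=5.0, intensity=100.0),)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _lesion_mask(lesion, shape: tuple[int, int, int]) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    if isinstance(lesion, Sphere):
        cz, cy, cx = lesion.center
        r = lesion.radius
        if not all(
            0 <= c - r and c + r <= dim - 1
            for c, dim in zip(lesion.center, shape)
        ):
            raise ValueError(f"sphere {lesion} extends outside the grid")
        d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
        return d2 <= r**2
    if isinstance(lesion, Box):
        if any(lo < 0 for lo in lesion.lower) or any(
            up > dim for up, dim in zip(lesion.upper, shape)
        ):
            raise ValueError(f"box {lesion} extends outside the grid")
        m = np.zeros(shape, dtype=bool)
        m[tuple(slice(lo, up) for lo, up in zip(lesion.lower, lesion.upper))] = True
        return m
    raise TypeError(f"unknown lesion type: {type(lesion).__name__}")


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, SegmentationMask]:
    """Deterministic phantom volume + exact lesion mask.

    Gaussian noise (sd in HU) is added voxelwise and the result rounded
    to integer HU, clipped at −1024.
    """
    rng = np.random.default_rng(spec.seed)
    voxels = np.full(spec.shape, spec.background, dtype=np.float64)
    mask = np.zeros(spec.shape, dtype=bool)
    for lesion in spec.lesions:
        lm = _lesion_mask(lesion, spec.shape)
        voxels[lm] = lesion.intensity
        mask |= lm
    if spec.noise_sd > 0:
        voxels = voxels + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    voxels = np.clip(np.round(voxels), -1024, 64511)
    volume = ImageVolume(
        voxels=voxels,
        spacing=spec.spacing,
        origin=(0.0, 0.0, 0.0),
        orientation=(1.0, 0.0, 0.0, 0.0, 1.0, 0.0),
        modality="CT",
    )
    seg = SegmentationMask(
        voxels=mask,
        label_name="lesion",
        parent_shape=volume.shape,
        parent_spacing=volume.spacing,
    )
    return volume, seg


def write_phantom_dicom(
    spec: PhantomSpec, directory: str | Path
) -> tuple[Path, Path]:
    """Write a phantom as a DICOM series plus a multi-frame mask file."""
    directory = Path(directory)
    volume, mask = generate_phantom(spec)
    series_dir = directory / "series"
    write_dicom_series(volume, series_dir)
    mask_path = write_mask(mask, directory / "mask.dcm")
    return series_dir, mask_path


@dataclass(frozen=True)
class TableSpec:
    """Spec for a synthetic cohort feature table.

    ``effects`` maps informative feature index -> standardized class
    effect (class 1 mean is shifted by effect * noise_sd).  Batches get
    additive shifts ``batch_shifts`` and multiplicative scales
    ``batch_scales`` applied to every feature.
    """

    n_per_class: tuple[int, int] = (63, 28)  # (class 0, class 1)
    n_features: int = 20
    effects: tuple[tuple[int, float], ...] = ()
    batch_sizes: tuple[int, ...] = (19, 50, 13, 5, 4)
    batch_shifts: tuple[float, ...] | None = None
    batch_scales: tuple[float, ...] | None = None
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_class) < 2:
            raise ValueError("need at least 2 samples per class")
        if sum(self.batch_sizes) != sum(self.n_per_class):
            raise ValueError(
                f"batch sizes sum to {sum(self.batch_sizes)} but cohort has "
                f"{sum(self.n_per_class)} samples"
            )
        if min(self.batch_sizes) < 2:
            raise ValueError("every batch needs at least 2 samples")
        for idx, _ in self.effects:
            if not 0 <= idx < self.n_features:
                raise ValueError(f"informative feature index out of range: {idx}")


DEFAULT_TABLE_SPEC = TableSpec()


def generate_feature_table(spec: TableSpec) -> tuple[pd.DataFrame, dict]:
    """Synthetic cohort table + ground-truth record.

    Features are i.i.d. N(0, noise_sd^2); class-1 rows are shifted by
    effect * noise_sd on the informative features; batch k is then
    distorted as ``x * scale_k + shift_k``.  Batch membership is a
    seeded random assignment honouring the batch sizes.
    """
    rng = np.random.default_rng(spec.seed)
    n0, n1 = spec.n_per_class
    n = n0 + n1
    p = spec.n_features
    x = rng.normal(0.0, spec.noise_sd, size=(n, p))
    y = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    for idx, effect in spec.effects:
        x[y == 1, idx] += effect * spec.noise_sd

    n_batches = len(spec.batch_sizes)
    shifts = np.asarray(
        spec.batch_shifts
        if spec.batch_shifts is not None
        else np.zeros(n_batches),
        dtype=float,
    )
    scales = np.asarray(
        spec.batch_scales
        if spec.batch_scales is not None
        else np.ones(n_batches),
        dtype=float,
    )
    if len(shifts) != n_batches or len(scales) != n_batches:
        raise ValueError("batch_shifts/batch_scales must match batch_sizes")

    batch_of = np.repeat(np.arange(n_batches), spec.batch_sizes)
    batch_of = batch_of[rng.permutation(n)]
    for b in range(n_batches):
        rows = batch_of == b
        x[rows] = x[rows] * scales[b] + shifts[b]

    table = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "label": y,
            "batch": (batch_of + 1).astype(int),
        }
    )
    for j in range(p):
        table[f"feat_{j:03d}"] = x[:, j]
    truth = {
        "informative": {f"feat_{idx:03d}": eff for idx, eff in spec.effects},
        "batch_shifts": shifts.tolist(),
        "batch_scales": scales.tolist(),
        "batch_sizes": list(spec.batch_sizes),
        "seed": spec.seed,
    }
    return table, truth
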