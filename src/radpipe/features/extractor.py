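"""Radiomic feature extraction from a volume + mask.

The default configuration enables all seven original-image feature
classes (shape, first order, GLCM, GLRLM, GLSZM, GLDM, NGTDM) with a
fixed bin width of 64 grey units, no resampling and no image filters,
yielding exactly 107 named features::

    shape 14 + firstorder 18 + glcm 24 + glrlm 16 + glszm 16
    + gldm 14 + ngtdm 5  =  107

Feature names follow the ``original_<class>_<FeatureName>`` scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..image_io import ImageVolume, SegmentationMask
from .discretize import DiscretizedRoi, discretize
from .firstorder import FIRSTORDER_FEATURES, firstorder_features
from .shape import SHAPE_FEATURES, shape_features
from .texture import (
    GLCM_FEATURES,
    GLDM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGTDM_FEATURES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = [
    "ExtractionSettings",
    "DEFAULT_CLASSES",
    "FEATURE_COUNTS",
    "feature_names",
    "compute_feature_class",
    "extract_features",
    "extract_cohort",
]

DEFAULT_CLASSES = (
    "shape",
    "firstorder",
    "glcm",
    "glrlm",
    "glszm",
    "gldm",
    "ngtdm",
)

FEATURE_COUNTS = {
    "shape": len(SHAPE_FEATURES),
    "firstorder": len(FIRSTORDER_FEATURES),
    "glcm": len(GLCM_FEATURES),
    "glrlm": len(GLRLM_FEATURES),
    "glszm": len(GLSZM_FEATURES),
    "gldm": len(GLDM_FEATURES),
    "ngtdm": len(NGTDM_FEATURES),
}

_CLASS_LISTS = {
    "shape": SHAPE_FEATURES,
    "firstorder": FIRSTORDER_FEATURES,
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "gldm": GLDM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
}


@dataclass(frozen=True)
class ExtractionSettings:
    """Extraction configuration.

    ``bin_width`` is the fixed bin width in grey units (HU for CT);
    ``classes`` lists the enabled feature classes in output order;
    ``gldm_alpha`` is the dependence tolerance.  Resampling and image
    filters are intentionally unsupported (original image only).
    """

    bin_width: float = 64.0
    classes: tuple[str, ...] = DEFAULT_CLASSES
    gldm_alpha: int = 0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        unknown = set(self.classes) - set(DEFAULT_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "bin_width": self.bin_width,
            "classes": list(self.classes),
            "gldm_alpha": self.gldm_alpha,
            "resampling": None,
            "filters": [],
        }


def feature_names(settings: ExtractionSettings | None = None) -> list[str]:
    """Canonical ordered feature names for a configuration."""
    settings = settings or ExtractionSettings()
    names = []
    for cls in settings.classes:
        names.extend(f"original_{cls}_{n}" for n in _CLASS_LISTS[cls])
    return names


def compute_feature_class(
    volume: ImageVolume,
    mask: SegmentationMask,
    feature_class: str,
    settings: ExtractionSettings | None = None,
    roi: DiscretizedRoi | None = None,
) -> dict[str, float]:
    """Compute all default features of one class.

    Shape features use the undiscretized mask geometry; first-order
    features use raw intensities (Entropy/Uniformity the discretized
    bins); texture classes use the discretized ROI.
    """
    settings = settings or ExtractionSettings()
    if mask.is_empty:
        raise ValueError("cannot extract features from an empty mask")
    mask.check_aligned(volume)
    if feature_class == "shape":
        return shape_features(mask.voxels, volume.axis_spacing)
    if roi is None:
        roi = discretize(volume, mask, settings.bin_width)
    if roi.n_levels == 1 and feature_class != "firstorder":
        warnings.warn(
            "single grey level in ROI: entropy- and correlation-type "
            "features are 0 by convention",
            stacklevel=2,
        )
    if feature_class == "firstorder":
        return firstorder_features(
            volume.voxels[mask.voxels], roi, volume.voxel_volume
        )
    if feature_class == "glcm":
        return glcm_features(roi)
    if feature_class == "glrlm":
        return glrlm_features(roi)
    if feature_class == "glszm":
        return glszm_features(roi)
    if feature_class == "gldm":
        return gldm_features(roi, alpha=settings.gldm_alpha)
    if feature_class == "ngtdm":
        return ngtdm_features(roi)
    raise ValueError(f"unknown feature class: {feature_class!r}")


def extract_features(
    volume: ImageVolume,
    mask: SegmentationMask,
    settings: ExtractionSettings | None = None,
) -> dict[str, float]:
    """Extract the configured feature vector (default: 107 features)."""
    settings = settings or ExtractionSettings()
    if mask.is_empty:
        raise ValueError("cannot extract features from an empty mask")
    mask.check_aligned(volume)
    roi = None
    if any(cls != "shape" for cls in settings.classes):
        roi = discretize(volume, mask, settings.bin_width)
    out: dict[str, float] = {}
    for cls in settings.classes:
        out.update(
            compute_feature_class(volume, mask, cls, settings, roi=roi)
        )
    return out


def extract_cohort(
    studies: list[tuple],
    settings: ExtractionSettings | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Extract features for a cohort of patients.

    ``studies`` is a list of ``(volume, mask, patient_id, label, batch)``
    tuples (``batch`` may be None).  Returns a table with one row per
    patient: ``patient_id``, ``label``, ``batch`` then the feature
    columns.  When ``out_dir`` is given, a per-patient CSV and a cohort
    CSV are written there.

    Raises on duplicate patient ids and on empty masks (naming the
    patient).
    """
    if not studies:
        raise ValueError("cohort is empty")
    settings = settings or ExtractionSettings()
    seen: set[str] = set()
    rows = []
    out_path = Path(out_dir) if out_dir is not None else None
    for volume, mask, patient_id, label, batch in studies:
        patient_id = str(patient_id)
        if patient_id in seen:
            raise ValueError(f"duplicate patient id: {patient_id}")
        seen.add(patient_id)
        if mask.is_empty:
            raise ValueError(f"empty mask for patient {patient_id}")
        features = extract_features(volume, mask, settings)
        row = {"patient_id": patient_id, "label": label, "batch": batch}
        row.update(features)
        rows.append(row)
        if out_path is not None:
            out_path.mkdir(parents=True, exist_ok=True)
            pd.DataFrame([features]).to_csv(
                out_path / f"{patient_id}.csv", index=False
            )
    table = pd.DataFrame(rows)
    if out_path is not None:
        table.to_csv(out_path / "cohort.csv", index=False)
    return table
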