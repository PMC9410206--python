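"""Radiomics study folders and JSON metadata.

A *study* is a directory holding everything a radiomics analysis
produced — per-patient feature CSVs, the cohort table, selection
reports, models and figures — together with ``metadata.json``, which
records every option set at every workflow stage (modality, extraction
settings, harmonization, selection, model and CV settings, seeds).  The
metadata is written as canonical JSON (sorted keys, fixed indentation)
so that studies diff cleanly and byte-equality implies setting
equality.  A study can be shared: importing an external study merges
its cohort rows when the extraction-relevant settings match, and an
empty target study auto-configures itself from the source metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .tables import read_cohort_csv, write_cohort_csv

__all__ = [
    "Study",
    "StudyError",
    "SettingsMismatchError",
    "create_study",
    "load_study",
    "import_external_study",
    "canonical_json",
]

SUBDIRS = ("features", "selection", "models", "reports")

# attributes that must agree for feature tables to be mergeable
EXTRACTION_KEYS = ("modality", "bin_width", "feature_classes", "resampling")


class StudyError(ValueError):
    pass


class SettingsMismatchError(StudyError):
    """Extraction settings of two studies differ; lists the attributes."""

    def __init__(self, differing: dict):
        self.differing = differing
        detail = "; ".join(
            f"{k}: {a!r} != {b!r}" for k, (a, b) in sorted(differing.items())
        )
        super().__init__(f"extraction settings mismatch ({detail})")


def canonical_json(obj) -> str:
    """Canonical serialization: sorted keys, 2-space indent, trailing \\n."""
    return json.dumps(obj, sort_keys=True, indent=2, allow_nan=False) + "\n"


def _default_metadata(name: str) -> dict:
    return {
        "name": name,
        "software_version": __version__,
        "modality": None,
        "import_options": {},
        "segmentation": {},
        "extraction": {
            "modality": None,
            "bin_width": None,
            "feature_classes": None,
            "resampling": None,
        },
        "harmonization": {"enabled": False},
        "selection": {},
        "model": {},
        "seeds": {},
    }


@dataclass
class Study:
    root: Path
    metadata: dict

    @property
    def metadata_path(self) -> Path:
        return self.root / "metadata.json"

    @property
    def cohort_path(self) -> Path:
        return self.root / "cohort.csv"

    @property
    def log_path(self) -> Path:
        return self.root / "log.jsonl"

    def path(self, *parts: str) -> Path:
        return self.root.joinpath(*parts)

    def save_metadata(self) -> None:
        self.metadata_path.write_text(canonical_json(self.metadata))

    def record(self, stage: str, settings: dict) -> None:
        """Record a stage's resolved settings and persist the metadata."""
        self.metadata.setdefault(stage, {})
        self.metadata[stage] = settings
        self.save_metadata()

    def log(self, subcommand: str, options: dict) -> None:
        """Append a timestamped entry to the study run log."""
        entry = {
            "time": datetime.now(timezone.utc).isoformat(),
            "subcommand": subcommand,
            "options": options,
        }
        with self.log_path.open("a") as fh:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")

    def load_cohort(self) -> pd.DataFrame | None:
        if self.cohort_path.exists():
            return read_cohort_csv(self.cohort_path)
        return None

    def save_cohort(self, table: pd.DataFrame) -> Path:
        return write_cohort_csv(table, self.cohort_path)

    def extraction_settings(self) -> dict:
        return {
            k: self.metadata.get("extraction", {}).get(k)
            for k in EXTRACTION_KEYS
        }

    def is_configured(self) -> bool:
        return any(v is not None for v in self.extraction_settings().values())


def create_study(root_path: str | Path, name: str, resume: bool = False) -> Study:
    """Create (or resume) a study directory skeleton."""
    root = Path(root_path) / name
    if root.exists() and (root / "metadata.json").exists():
        if not resume:
            raise StudyError(
                f"study already exists at {root}; pass resume=True to reopen"
            )
        return load_study(root)
    root.mkdir(parents=True, exist_ok=True)
    for sub in SUBDIRS:
        (root / sub).mkdir(exist_ok=True)
    study = Study(root=root, metadata=_default_metadata(name))
    study.save_metadata()
    return study


def load_study(root: str | Path) -> Study:
    root = Path(root)
    meta_path = root / "metadata.json"
    if not meta_path.exists():
        raise StudyError(f"no study metadata at {meta_path}")
    return Study(root=root, metadata=json.loads(meta_path.read_text()))


def import_external_study(target: Study, source: str | Path) -> pd.DataFrame:
    """Merge an external study's cohort into ``target``.

    The extraction-relevant settings (modality, bin width, enabled
    feature classes, resampling) must match; a mismatch is rejected
    listing every differing attribute.  An unconfigured target adopts
    the source settings.  Duplicate patient ids are rejected by id.
    Returns (and persists) the merged cohort table.
    """
    src = load_study(source)
    src_settings = src.extraction_settings()
    if not target.is_configured():
        target.metadata["extraction"] = dict(
            src.metadata.get("extraction", {})
        )
        target.save_metadata()
    else:
        tgt_settings = target.extraction_settings()
        differing = {
            k: (tgt_settings[k], src_settings[k])
            for k in EXTRACTION_KEYS
            if tgt_settings[k] != src_settings[k]
        }
        if differing:
            raise SettingsMismatchError(differing)

    src_cohort = src.load_cohort()
    if src_cohort is None:
        raise StudyError(f"source study has no cohort table: {src.root}")
    tgt_cohort = target.load_cohort()
    if tgt_cohort is None:
        merged = src_cohort.copy()
    else:
        overlap = set(tgt_cohort["patient_id"]) & set(src_cohort["patient_id"])
        if overlap:
            raise StudyError(
                f"duplicate patient ids across studies: {sorted(overlap)}"
            )
        if list(tgt_cohort.columns) != list(src_cohort.columns):
            raise StudyError("cohort tables have different columns")
        merged = pd.concat([tgt_cohort, src_cohort], ignore_index=True)
    target.save_cohort(merged)
    return merged
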