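"""Semi-automatic target segmentation.

The segmentation primitive is percentage-of-maximum thresholding inside a
rectangular volume of interest (VOI): a voxel belongs to the target when
its intensity is at least ``percent/100`` of the brightest voxel in the
VOI.  Basic mask algebra (add / erase over a box region) stands in for
interactive correction tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import ImageVolume, SegmentationMask

__all__ = ["VoiBox", "threshold_segment", "mask_edit"]


@dataclass(frozen=True)
class VoiBox:
    """An axis-aligned box in voxel indices: inclusive lower, exclusive upper."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.lower) != 3 or len(self.upper) != 3:
            raise ValueError("VoiBox corners must have three components")
        if any(lo >= up for lo, up in zip(self.lower, self.upper)):
            raise ValueError("VoiBox must satisfy lower < upper on every axis")
        if any(lo < 0 for lo in self.lower):
            raise ValueError("VoiBox lower corner must be non-negative")

    def check_within(self, shape: tuple[int, int, int]) -> None:
        if any(up > dim for up, dim in zip(self.upper, shape)):
            raise ValueError(
                f"VoiBox upper corner {self.upper} exceeds grid shape {shape}"
            )

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, up) for lo, up in zip(self.lower, self.upper))

    @property
    def volume(self) -> int:
        return int(np.prod([up - lo for lo, up in zip(self.lower, self.upper)]))


def threshold_segment(
    volume: ImageVolume, voi: VoiBox, percent: float, label_name: str = "lesion"
) -> SegmentationMask:
    """Segment by thresholding at a percentage of the VOI maximum.

    Foreground = voxels inside ``voi`` whose value is >= (percent/100) x
    the maximum value in the VOI.  The comparison is inclusive, so
    ``percent=100`` always yields the maximal voxel(s) and a uniform VOI
    is segmented whole for any percentage.
    """
    if not 0 < percent <= 100:
        raise ValueError(f"percent must lie in (0, 100], got {percent}")
    voi.check_within(volume.shape)
    region = volume.voxels[voi.slices]
    threshold = (percent / 100.0) * float(region.max())
    mask = np.zeros(volume.shape, dtype=bool)
    mask[voi.slices] = region >= threshold
    return SegmentationMask(
        voxels=mask,
        label_name=label_name,
        parent_shape=volume.shape,
        parent_spacing=volume.spacing,
    )


def mask_edit(mask: SegmentationMask, region: VoiBox, mode: str) -> SegmentationMask:
    """Set a box region to foreground (``add``) or background (``erase``)."""
    if mode not in ("add", "erase"):
        raise ValueError(f"mode must be 'add' or 'erase', got {mode!r}")
    region.check_within(mask.voxels.shape)
    voxels = mask.voxels.copy()
    voxels[region.slices] = mode == "add"
    return SegmentationMask(
        voxels=voxels,
        label_name=mask.label_name,
        parent_shape=mask.parent_shape,
        parent_spacing=mask.parent_spacing,
    )
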