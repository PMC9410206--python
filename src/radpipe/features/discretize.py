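"""Fixed-bin-width intensity discretization of a region of interest.

Grey levels inside the mask are mapped to integer bins of constant width
anchored at the ROI minimum::

    bin(v) = floor((v - min_ROI) / bin_width) + 1

so the dimmest voxel always falls in bin 1 and a constant intensity shift
leaves every bin index unchanged.  Bin indices are 1-based; 0 marks
voxels outside the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..image_io import ImageVolume, SegmentationMask

__all__ = ["DiscretizedRoi", "discretize"]


@dataclass
class DiscretizedRoi:
    """Binned intensities of a masked region, cropped to its bounding box.

    Attributes
    ----------
    bins : ndarray of int
        Bin index per voxel (1-based); 0 outside the mask.
    mask : ndarray of bool
        Foreground map, same shape as ``bins``.
    bin_width : float
        Bin width in grey units.
    anchor : float
        ROI minimum intensity (left edge of bin 1).
    n_levels : int
        Largest bin index present.
    spacing : tuple of float
        Voxel spacing ordered like the array axes (slice, row, column).
    """

    bins: np.ndarray
    mask: np.ndarray
    bin_width: float
    anchor: float
    n_levels: int
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def masked_bins(self) -> np.ndarray:
        """Bin indices of the foreground voxels (1D)."""
        return self.bins[self.mask]

    @property
    def levels(self) -> np.ndarray:
        """Distinct bin values present in the ROI, ascending."""
        return np.unique(self.masked_bins)


def _crop_to_mask(mask: np.ndarray) -> tuple[slice, ...]:
    coords = np.nonzero(mask)
    return tuple(
        slice(int(c.min()), int(c.max()) + 1) for c in coords
    )


def discretize(
    volume: ImageVolume, mask: SegmentationMask, bin_width: float
) -> DiscretizedRoi:
    """Discretize the masked intensities with a fixed bin width."""
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    mask.check_aligned(volume)
    if mask.is_empty:
        raise ValueError("cannot discretize an empty mask")

    bbox = _crop_to_mask(mask.voxels)
    sub_mask = mask.voxels[bbox]
    sub_vox = volume.voxels[bbox]
    anchor = float(sub_vox[sub_mask].min())
    bins = np.zeros(sub_mask.shape, dtype=np.int64)
    bins[sub_mask] = (
        np.floor((sub_vox[sub_mask] - anchor) / bin_width).astype(np.int64) + 1
    )
    return DiscretizedRoi(
        bins=bins,
        mask=sub_mask,
        bin_width=float(bin_width),
        anchor=anchor,
        n_levels=int(bins.max()),
        spacing=volume.axis_spacing,
    )


def discretize_array(
    values: np.ndarray,
    mask: np.ndarray,
    bin_width: float,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> DiscretizedRoi:
    """Array-level variant of :func:`discretize`, for tests and tools."""
    vol = ImageVolume(
        voxels=np.asarray(values, dtype=float),
        spacing=(spacing[1], spacing[2], spacing[0]),
        origin=(0.0, 0.0, 0.0),
        orientation=(1, 0, 0, 0, 1, 0),
    )
    m = SegmentationMask(voxels=np.asarray(mask), parent_shape=vol.shape)
    return discretize(vol, m, bin_width)
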