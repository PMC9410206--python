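"""Grey-level texture matrices.

Builders for the five classical texture-matrix families over a
discretized ROI:

* GLCM — grey-level co-occurrence: symmetrized pair counts at distance 1
  along the 13 unique 3D directions, normalized per direction.
* GLRLM — grey-level run lengths per direction (runs break at mask
  boundaries and grid edges).
* GLSZM — grey-level size zones: connected components of equal grey
  level under 26-connectivity.
* GLDM — grey-level dependence: for each voxel, the number of 26-
  neighbours inside the mask whose grey level differs by at most a
  tolerance alpha (default 0); the dependence size counts the centre
  voxel itself, so it is always >= 1.
* NGTDM — neighbourhood grey-tone difference: per grey level, the summed
  absolute difference between the level and the mean grey level of each
  voxel's masked 26-neighbourhood.

Matrices are indexed by actual bin value (rows 1..n_levels); rows for
absent levels are zero.  Feature formulas consume the actual level
values, and counts of "distinct levels" include only levels present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedRoi

__all__ = [
    "TextureMatrix",
    "DIRECTIONS_13",
    "OFFSETS_26",
    "glcm_matrices",
    "glrlm_matrices",
    "glszm_matrix",
    "gldm_matrix",
    "ngtdm_table",
    "compute_texture_matrix",
]

# The 13 unique nearest-neighbour directions in 3D (half of the 26
# neighbour offsets, keeping the lexicographically positive member of
# each +/- pair).  Offsets are in array axis order (slice, row, column).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    d
    for d in product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0) and d > (0, 0, 0)
)

# All 26 neighbour offsets.
OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
)


@dataclass
class TextureMatrix:
    """A texture matrix with its family tag and build parameters."""

    family: str
    values: np.ndarray
    parameters: dict = field(default_factory=dict)


def _shifted_views(arr: np.ndarray, offset: tuple[int, int, int]):
    """Overlapping views of ``arr`` for voxel pairs separated by ``offset``."""
    src = []
    dst = []
    for o, dim in zip(offset, arr.shape):
        if o >= 0:
            src.append(slice(0, dim - o))
            dst.append(slice(o, dim))
        else:
            src.append(slice(-o, dim))
            dst.append(slice(0, dim + o))
    return arr[tuple(src)], arr[tuple(dst)]


def glcm_matrices(roi: DiscretizedRoi, distance: int = 1) -> list[np.ndarray]:
    """Symmetrized, per-direction-normalized co-occurrence matrices.

    Returns one (n_levels x n_levels) matrix per direction in
    :data:`DIRECTIONS_13`; directions with no valid voxel pair yield a
    zero matrix.
    """
    ng = roi.n_levels
    bins = roi.bins
    out = []
    for direction in DIRECTIONS_13:
        offset = tuple(distance * d for d in direction)
        a, b = _shifted_views(bins, offset)
        valid = (a > 0) & (b > 0)
        counts = np.zeros((ng, ng), dtype=np.float64)
        if valid.any():
            i = a[valid] - 1
            j = b[valid] - 1
            np.add.at(counts, (i, j), 1.0)
            counts = counts + counts.T  # symmetrize
            counts /= counts.sum()
        out.append(counts)
    return out


def _runs_along_direction(
    bins: np.ndarray, direction: tuple[int, int, int]
) -> np.ndarray:
    """Run-length matrix (n_levels x max_run) for one direction."""
    ng = int(bins.max())
    shape = bins.shape
    max_run = int(np.ceil(np.sqrt(sum(s**2 for s in shape)))) + 1
    counts = np.zeros((ng, max_run), dtype=np.float64)
    dz, dy, dx = direction
    # line starts: voxels whose predecessor along the direction is outside
    for z in range(shape[0]):
        pz = z - dz
        for y in range(shape[1]):
            py = y - dy
            for x in range(shape[2]):
                px = x - dx
                if (
                    0 <= pz < shape[0]
                    and 0 <= py < shape[1]
                    and 0 <= px < shape[2]
                ):
                    continue  # not a line start
                # walk the line, splitting into runs of equal nonzero value
                cz, cy, cx = z, y, x
                current = 0
                length = 0
                while 0 <= cz < shape[0] and 0 <= cy < shape[1] and 0 <= cx < shape[2]:
                    v = bins[cz, cy, cx]
                    if v == current:
                        length += 1
                    else:
                        if current > 0:
                            counts[current - 1, length - 1] += 1
                        current = int(v)
                        length = 1
                    cz += dz
                    cy += dy
                    cx += dx
                if current > 0:
                    counts[current - 1, length - 1] += 1
    # trim trailing all-zero run-length columns
    nonzero_cols = np.nonzero(counts.sum(axis=0))[0]
    last = nonzero_cols[-1] + 1 if nonzero_cols.size else 1
    return counts[:, :last]


def glrlm_matrices(roi: DiscretizedRoi) -> list[np.ndarray]:
    """Run-length matrices for the 13 unique directions (raw counts)."""
    return [_runs_along_direction(roi.bins, d) for d in DIRECTIONS_13]


def glszm_matrix(roi: DiscretizedRoi) -> np.ndarray:
    """Size-zone matrix (n_levels x max_zone_size) under 26-connectivity."""
    structure = np.ones((3, 3, 3), dtype=int)
    ng = roi.n_levels
    zones: list[tuple[int, int]] = []
    max_size = 1
    for level in roi.levels:
        labelled, n = ndimage.label(roi.bins == level, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(labelled.ravel())[1:]
        for s in sizes:
            zones.append((int(level), int(s)))
            max_size = max(max_size, int(s))
    counts = np.zeros((ng, max_size), dtype=np.float64)
    for level, size in zones:
        counts[level - 1, size - 1] += 1
    return counts


def gldm_matrix(roi: DiscretizedRoi, alpha: int = 0) -> np.ndarray:
    """Dependence matrix (n_levels x 27): entry (i, j) counts voxels of
    level i with dependence size j (centre voxel + dependent neighbours).
    """
    bins = roi.bins
    dependence = np.zeros(bins.shape, dtype=np.int64)
    for offset in OFFSETS_26:
        src_sl, dst_sl = _shifted_views_slices(bins.shape, offset)
        a = bins[src_sl]  # centre view
        b = bins[dst_sl]  # neighbour view
        dep = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
        dependence[src_sl] += dep
    ng = roi.n_levels
    counts = np.zeros((ng, 27), dtype=np.float64)
    m = roi.mask
    np.add.at(counts, (bins[m] - 1, dependence[m]), 1.0)
    nonzero_cols = np.nonzero(counts.sum(axis=0))[0]
    last = nonzero_cols[-1] + 1 if nonzero_cols.size else 1
    return counts[:, :last]


def _shifted_views_slices(shape, offset):
    src = []
    dst = []
    for o, dim in zip(offset, shape):
        if o >= 0:
            src.append(slice(0, dim - o))
            dst.append(slice(o, dim))
        else:
            src.append(slice(-o, dim))
            dst.append(slice(0, dim + o))
    return tuple(src), tuple(dst)


def ngtdm_table(roi: DiscretizedRoi) -> dict[str, np.ndarray]:
    """Neighbourhood grey-tone difference table.

    Returns per-level arrays ``n`` (voxel counts), ``p`` (probabilities)
    and ``s`` (summed absolute differences from the neighbourhood mean),
    indexed 0..n_levels-1.  Only voxels with at least one masked
    neighbour contribute.
    """
    bins = roi.bins
    nbr_sum = np.zeros(bins.shape, dtype=np.float64)
    nbr_cnt = np.zeros(bins.shape, dtype=np.int64)
    for offset in OFFSETS_26:
        src_sl, dst_sl = _shifted_views_slices(bins.shape, offset)
        a = bins[src_sl]  # centre view
        b = bins[dst_sl]  # neighbour view
        contrib = (a > 0) & (b > 0)
        nbr_sum[src_sl] += np.where(contrib, b, 0)
        nbr_cnt[src_sl] += contrib
    ng = roi.n_levels
    n = np.zeros(ng, dtype=np.float64)
    s = np.zeros(ng, dtype=np.float64)
    valid = roi.mask & (nbr_cnt > 0)
    levels = bins[valid]
    diffs = np.abs(levels - nbr_sum[valid] / nbr_cnt[valid])
    np.add.at(n, levels - 1, 1.0)
    np.add.at(s, levels - 1, diffs)
    total = n.sum()
    p = n / total if total > 0 else n.copy()
    return {"n": n, "p": p, "s": s, "n_valid": float(total)}


def compute_texture_matrix(
    roi: DiscretizedRoi, family: str, **params
) -> TextureMatrix:
    """Build one texture matrix (or per-direction stack) by family tag."""
    family = family.lower()
    if family == "glcm":
        mats = glcm_matrices(roi, distance=params.get("distance", 1))
        return TextureMatrix(
            family="GLCM",
            values=np.stack(mats),
            parameters={"distance": params.get("distance", 1),
                        "directions": DIRECTIONS_13, "symmetric": True},
        )
    if family == "glrlm":
        mats = glrlm_matrices(roi)
        width = max(m.shape[1] for m in mats)
        padded = [
            np.pad(m, ((0, 0), (0, width - m.shape[1]))) for m in mats
        ]
        return TextureMatrix(
            family="GLRLM", values=np.stack(padded),
            parameters={"directions": DIRECTIONS_13},
        )
    if family == "glszm":
        return TextureMatrix(
            family="GLSZM", values=glszm_matrix(roi),
            parameters={"connectivity": 26},
        )
    if family == "gldm":
        alpha = params.get("alpha", 0)
        return TextureMatrix(
            family="GLDM", values=gldm_matrix(roi, alpha=alpha),
            parameters={"alpha": alpha, "distance": 1},
        )
    if family == "ngtdm":
        table = ngtdm_table(roi)
        return TextureMatrix(
            family="NGTDM",
            values=np.column_stack([table["n"], table["p"], table["s"]]),
            parameters={"distance": 1, "columns": ("n", "p", "s")},
        )
    raise ValueError(f"unknown texture-matrix family: {family!r}")
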