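"""Independent brute-force texture-feature oracle.

Pure-Python, dictionary-and-loop re-implementation of the five texture
families, written against the matrix definitions directly and kept
deliberately free of the vectorized package code so it can serve as an
independent reference on tiny ROIs.  Shares only the public conventions
(13 symmetric directions, actual bin values as grey levels, entropies
over positive entries, per-direction feature averaging).
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

# independently enumerated half-space of the 26 neighbour offsets
DIRECTIONS = []
for dz in (0, 1):
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dz == 0 and (dy, dx) <= (0, 0):
                continue
            DIRECTIONS.append((dz, dy, dx))
assert len(DIRECTIONS) == 13

NEIGHBOURS_26 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]


def _inside(shape, z, y, x):
    return 0 <= z < shape[0] and 0 <= y < shape[1] and 0 <= x < shape[2]


def _entropy(values):
    return -sum(p * math.log2(p) for p in values if p > 0)


# ---------------------------------------------------------------- GLCM


def _glcm_pairs(bins, direction):
    """Symmetric co-occurrence dict {(i, j): count} for one direction."""
    shape = bins.shape
    pairs = defaultdict(float)
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                i = int(bins[z, y, x])
                if i == 0:
                    continue
                z2, y2, x2 = z + direction[0], y + direction[1], x + direction[2]
                if not _inside(shape, z2, y2, x2):
                    continue
                j = int(bins[z2, y2, x2])
                if j == 0:
                    continue
                pairs[(i, j)] += 1.0
                pairs[(j, i)] += 1.0
    return dict(pairs)


def _glcm_features_single(pairs):
    total = sum(pairs.values())
    p = {ij: c / total for ij, c in pairs.items()}
    px = defaultdict(float)
    py = defaultdict(float)
    for (i, j), v in p.items():
        px[i] += v
        py[j] += v
    ng = len(px)
    mu_x = sum(i * v for i, v in px.items())
    mu_y = sum(j * v for j, v in py.items())
    sig_x = math.sqrt(sum(v * (i - mu_x) ** 2 for i, v in px.items()))
    sig_y = math.sqrt(sum(v * (j - mu_y) ** 2 for j, v in py.items()))
    p_diff = defaultdict(float)
    p_sum = defaultdict(float)
    for (i, j), v in p.items():
        p_diff[abs(i - j)] += v
        p_sum[i + j] += v
    diff_avg = sum(k * v for k, v in p_diff.items())

    out = {}
    out["Autocorrelation"] = sum(v * i * j for (i, j), v in p.items())
    out["JointAverage"] = mu_x
    for name, power in (
        ("ClusterProminence", 4),
        ("ClusterShade", 3),
        ("ClusterTendency", 2),
    ):
        out[name] = sum(
            v * (i + j - mu_x - mu_y) ** power for (i, j), v in p.items()
        )
    out["Contrast"] = sum(v * (i - j) ** 2 for (i, j), v in p.items())
    if sig_x > 0 and sig_y > 0:
        out["Correlation"] = (
            sum(v * i * j for (i, j), v in p.items()) - mu_x * mu_y
        ) / (sig_x * sig_y)
    else:
        out["Correlation"] = 0.0
    out["DifferenceAverage"] = diff_avg
    out["DifferenceEntropy"] = _entropy(p_diff.values())
    out["DifferenceVariance"] = sum(
        v * (k - diff_avg) ** 2 for k, v in p_diff.items()
    )
    out["Id"] = sum(v / (1 + abs(i - j)) for (i, j), v in p.items())
    out["Idm"] = sum(v / (1 + (i - j) ** 2) for (i, j), v in p.items())
    out["Idmn"] = sum(
        v / (1 + (i - j) ** 2 / ng**2) for (i, j), v in p.items()
    )
    out["Idn"] = sum(v / (1 + abs(i - j) / ng) for (i, j), v in p.items())
    out["InverseVariance"] = sum(
        v / (i - j) ** 2 for (i, j), v in p.items() if i != j
    )
    out["JointEnergy"] = sum(v * v for v in p.values())
    hxy = _entropy(p.values())
    out["JointEntropy"] = hxy
    hx = _entropy(px.values())
    hy = _entropy(py.values())
    hxy1 = -sum(
        v * math.log2(px[i] * py[j])
        for (i, j), v in p.items()
        if px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in px
        for j in py
        if px[i] * py[j] > 0
    )
    div = max(hx, hy)
    out["Imc1"] = (hxy - hxy1) / div if div > 0 else 0.0
    out["Imc2"] = (
        math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
        if ng > 1
        else 0.0
    )
    out["MCC"] = _mcc(p, px, py)
    out["MaximumProbability"] = max(p.values())
    out["SumAverage"] = sum(k * v for k, v in p_sum.items())
    out["SumEntropy"] = _entropy(p_sum.values())
    out["SumSquares"] = sum(v * (i - mu_x) ** 2 for (i, j), v in p.items())
    return out


def _mcc(p, px, py):
    levels = sorted(px)
    if len(levels) < 2:
        return 0.0
    q = np.zeros((len(levels), len(levels)))
    for a, i in enumerate(levels):
        for b, j in enumerate(levels):
            q[a, b] = sum(
                p.get((i, k), 0.0) * p.get((j, k), 0.0) / (px[i] * py[k])
                for k in levels
            )
    eig = sorted(np.linalg.eigvals(q).real)
    return math.sqrt(max(0.0, eig[-2]))


def oracle_glcm(bins):
    per_dir = []
    for d in DIRECTIONS:
        pairs = _glcm_pairs(bins, d)
        if pairs:
            per_dir.append(_glcm_features_single(pairs))
    names = per_dir[0].keys()
    return {
        f"original_glcm_{n}": sum(d[n] for d in per_dir) / len(per_dir)
        for n in names
    }


# --------------------------------------------------------------- GLRLM


def _runs(bins, direction):
    """Run dict {(level, length): count} for one direction."""
    shape = bins.shape
    runs = defaultdict(float)
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                prev = (z - direction[0], y - direction[1], x - direction[2])
                if _inside(shape, *prev):
                    continue
                cz, cy, cx = z, y, x
                current, length = 0, 0
                while _inside(shape, cz, cy, cx):
                    v = int(bins[cz, cy, cx])
                    if v == current:
                        length += 1
                    else:
                        if current > 0:
                            runs[(current, length)] += 1
                        current, length = v, 1
                    cz += direction[0]
                    cy += direction[1]
                    cx += direction[2]
                if current > 0:
                    runs[(current, length)] += 1
    return dict(runs)


def _size_features(entries, n_voxels):
    """Shared brute-force formulas over {(level, size): count} dicts."""
    ns = sum(entries.values())
    row = defaultdict(float)
    col = defaultdict(float)
    for (i, j), c in entries.items():
        row[i] += c
        col[j] += c
    mu_i = sum(i * c for (i, j), c in entries.items()) / ns
    mu_j = sum(j * c for (i, j), c in entries.items()) / ns
    return {
        "small": sum(c / j**2 for (i, j), c in entries.items()) / ns,
        "large": sum(c * j**2 for (i, j), c in entries.items()) / ns,
        "low": sum(c / i**2 for (i, j), c in entries.items()) / ns,
        "high": sum(c * i**2 for (i, j), c in entries.items()) / ns,
        "small_low": sum(
            c / (i**2 * j**2) for (i, j), c in entries.items()
        )
        / ns,
        "small_high": sum(
            c * i**2 / j**2 for (i, j), c in entries.items()
        )
        / ns,
        "large_low": sum(
            c * j**2 / i**2 for (i, j), c in entries.items()
        )
        / ns,
        "large_high": sum(
            c * i**2 * j**2 for (i, j), c in entries.items()
        )
        / ns,
        "gln": sum(v**2 for v in row.values()) / ns,
        "glnn": sum(v**2 for v in row.values()) / ns**2,
        "sn": sum(v**2 for v in col.values()) / ns,
        "snn": sum(v**2 for v in col.values()) / ns**2,
        "glv": sum(c / ns * (i - mu_i) ** 2 for (i, j), c in entries.items()),
        "sv": sum(c / ns * (j - mu_j) ** 2 for (i, j), c in entries.items()),
        "entropy": _entropy([c / ns for c in entries.values()]),
        "pct": ns / n_voxels,
    }


_GLRLM_MAP = {
    "GrayLevelNonUniformity": "gln",
    "GrayLevelNonUniformityNormalized": "glnn",
    "GrayLevelVariance": "glv",
    "HighGrayLevelRunEmphasis": "high",
    "LongRunEmphasis": "large",
    "LongRunHighGrayLevelEmphasis": "large_high",
    "LongRunLowGrayLevelEmphasis": "large_low",
    "LowGrayLevelRunEmphasis": "low",
    "RunEntropy": "entropy",
    "RunLengthNonUniformity": "sn",
    "RunLengthNonUniformityNormalized": "snn",
    "RunPercentage": "pct",
    "RunVariance": "sv",
    "ShortRunEmphasis": "small",
    "ShortRunHighGrayLevelEmphasis": "small_high",
    "ShortRunLowGrayLevelEmphasis": "small_low",
}

_GLSZM_MAP = {
    "GrayLevelNonUniformity": "gln",
    "GrayLevelNonUniformityNormalized": "glnn",
    "GrayLevelVariance": "glv",
    "HighGrayLevelZoneEmphasis": "high",
    "LargeAreaEmphasis": "large",
    "LargeAreaHighGrayLevelEmphasis": "large_high",
    "LargeAreaLowGrayLevelEmphasis": "large_low",
    "LowGrayLevelZoneEmphasis": "low",
    "SizeZoneNonUniformity": "sn",
    "SizeZoneNonUniformityNormalized": "snn",
    "SmallAreaEmphasis": "small",
    "SmallAreaHighGrayLevelEmphasis": "small_high",
    "SmallAreaLowGrayLevelEmphasis": "small_low",
    "ZoneEntropy": "entropy",
    "ZonePercentage": "pct",
    "ZoneVariance": "sv",
}

_GLDM_MAP = {
    "DependenceEntropy": "entropy",
    "DependenceNonUniformity": "sn",
    "DependenceNonUniformityNormalized": "snn",
    "DependenceVariance": "sv",
    "GrayLevelNonUniformity": "gln",
    "GrayLevelVariance": "glv",
    "HighGrayLevelEmphasis": "high",
    "LargeDependenceEmphasis": "large",
    "LargeDependenceHighGrayLevelEmphasis": "large_high",
    "LargeDependenceLowGrayLevelEmphasis": "large_low",
    "LowGrayLevelEmphasis": "low",
    "SmallDependenceEmphasis": "small",
    "SmallDependenceHighGrayLevelEmphasis": "small_high",
    "SmallDependenceLowGrayLevelEmphasis": "small_low",
}


def oracle_glrlm(bins):
    n_voxels = int((bins > 0).sum())
    per_dir = []
    for d in DIRECTIONS:
        runs = _runs(bins, d)
        if runs:
            per_dir.append(_size_features(runs, n_voxels))
    return {
        f"original_glrlm_{name}": sum(d[key] for d in per_dir) / len(per_dir)
        for name, key in _GLRLM_MAP.items()
    }


# --------------------------------------------------------------- GLSZM


def oracle_glszm(bins):
    shape = bins.shape
    n_voxels = int((bins > 0).sum())
    visited = np.zeros(shape, dtype=bool)
    zones = defaultdict(float)
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if visited[z, y, x] or bins[z, y, x] == 0:
                    continue
                level = int(bins[z, y, x])
                stack = [(z, y, x)]
                visited[z, y, x] = True
                size = 0
                while stack:
                    cz, cy, cx = stack.pop()
                    size += 1
                    for dz, dy, dx in NEIGHBOURS_26:
                        nz, ny, nx = cz + dz, cy + dy, cx + dx
                        if (
                            _inside(shape, nz, ny, nx)
                            and not visited[nz, ny, nx]
                            and int(bins[nz, ny, nx]) == level
                        ):
                            visited[nz, ny, nx] = True
                            stack.append((nz, ny, nx))
                zones[(level, size)] += 1
    vals = _size_features(zones, n_voxels)
    return {f"original_glszm_{n}": vals[k] for n, k in _GLSZM_MAP.items()}


# ---------------------------------------------------------------- GLDM


def oracle_gldm(bins, alpha=0):
    shape = bins.shape
    n_voxels = int((bins > 0).sum())
    entries = defaultdict(float)
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                i = int(bins[z, y, x])
                if i == 0:
                    continue
                dep = 0
                for dz, dy, dx in NEIGHBOURS_26:
                    nz, ny, nx = z + dz, y + dy, x + dx
                    if not _inside(shape, nz, ny, nx):
                        continue
                    j = int(bins[nz, ny, nx])
                    if j > 0 and abs(i - j) <= alpha:
                        dep += 1
                entries[(i, dep + 1)] += 1  # size counts the centre voxel
    vals = _size_features(entries, n_voxels)
    return {f"original_gldm_{n}": vals[k] for n, k in _GLDM_MAP.items()}


# --------------------------------------------------------------- NGTDM


def oracle_ngtdm(bins):
    shape = bins.shape
    n = defaultdict(float)
    s = defaultdict(float)
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                i = int(bins[z, y, x])
                if i == 0:
                    continue
                nb = [
                    int(bins[z + dz, y + dy, x + dx])
                    for dz, dy, dx in NEIGHBOURS_26
                    if _inside(shape, z + dz, y + dy, x + dx)
                    and bins[z + dz, y + dy, x + dx] > 0
                ]
                if not nb:
                    continue
                n[i] += 1
                s[i] += abs(i - sum(nb) / len(nb))
    n_valid = sum(n.values())
    p = {i: v / n_valid for i, v in n.items()}
    levels = sorted(p)
    ngp = len(levels)

    ps = sum(p[i] * s[i] for i in levels)
    out = {
        "Busyness": 0.0,
        "Coarseness": 1.0 / ps if ps > 0 else 1e6,
        "Complexity": 0.0,
        "Contrast": 0.0,
        "Strength": 0.0,
    }
    if ngp > 1:
        out["Contrast"] = (
            sum(
                p[i] * p[j] * (i - j) ** 2
                for i in levels
                for j in levels
            )
            / (ngp * (ngp - 1))
            * sum(s.values())
            / n_valid
        )
        denom = sum(
            abs(i * p[i] - j * p[j]) for i in levels for j in levels
        )
        out["Busyness"] = ps / denom if denom > 0 else 0.0
        out["Complexity"] = (
            sum(
                abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                for i in levels
                for j in levels
            )
            / n_valid
        )
        ssum = sum(s.values())
        out["Strength"] = (
            sum(
                (p[i] + p[j]) * (i - j) ** 2
                for i in levels
                for j in levels
            )
            / ssum
            if ssum > 0
            else 0.0
        )
    return {f"original_ngtdm_{k}": v for k, v in out.items()}


def oracle_all_texture(bins):
    """All five families on a 3D bin array (0 = outside mask)."""
    out = {}
    out.update(oracle_glcm(bins))
    out.update(oracle_glrlm(bins))
    out.update(oracle_glszm(bins))
    out.update(oracle_gldm(bins))
    out.update(oracle_ngtdm(bins))
    return out


def random_roi(rng, shape=(2, 5, 5), n_levels=4, hole_fraction=0.15):
    """Random small binned ROI with >=2 levels and optional mask holes."""
    while True:
        bins = rng.integers(1, n_levels + 1, size=shape)
        holes = rng.random(shape) < hole_fraction
        bins[holes] = 0
        present = np.unique(bins[bins > 0])
        if present.size >= 2 and (bins > 0).sum() >= 8:
            return bins
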