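"""Texture feature formulas.

Each family function consumes the matrices built in
:mod:`radpipe.features.matrices` and returns an ordered dict of feature
values using the canonical ``original_<class>_<FeatureName>`` names.

Conventions
-----------
* Feature formulas use the *actual* bin values as grey levels; counts of
  distinct levels (``Ng`` in normalized inverse-difference features)
  include only levels present in the ROI.
* Entropies are natural sums ``-sum p log2 p`` over strictly positive
  entries — no epsilon padding.
* For directional families (GLCM, GLRLM) the feature value is the mean
  of the per-direction values, skipping directions with no voxel pairs.
* Degenerate single-grey-level ROIs give 0 for entropy- and
  correlation-type features (a warning is emitted by the extractor).
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedRoi
from .matrices import glcm_matrices, gldm_matrix, glrlm_matrices, glszm_matrix, ngtdm_table

__all__ = [
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
    "GLCM_FEATURES",
    "GLRLM_FEATURES",
    "GLSZM_FEATURES",
    "GLDM_FEATURES",
    "NGTDM_FEATURES",
]

GLCM_FEATURES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)

GLRLM_FEATURES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)

GLSZM_FEATURES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
)

GLDM_FEATURES = (
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

NGTDM_FEATURES = (
    "Busyness",
    "Coarseness",
    "Complexity",
    "Contrast",
    "Strength",
)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p))) if p.size else 0.0


def _glcm_single(p: np.ndarray) -> dict[str, float]:
    ng_total = p.shape[0]
    i_vals = np.arange(1, ng_total + 1, dtype=float)
    ii, jj = np.meshgrid(i_vals, i_vals, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    present = px > 0
    ng = int(present.sum())
    mu_x = float(np.sum(px * i_vals))
    mu_y = float(np.sum(py * i_vals))
    sig_x = float(np.sqrt(np.sum(px * (i_vals - mu_x) ** 2)))
    sig_y = float(np.sqrt(np.sum(py * (i_vals - mu_y) ** 2)))

    # difference distribution p_{|i-j|}(k), k = 0..ng_total-1
    k_diff = np.arange(ng_total, dtype=float)
    p_diff = np.zeros(ng_total)
    np.add.at(p_diff, np.abs(ii - jj).astype(int), p)
    # sum distribution p_{i+j}(k), k = 2..2*ng_total
    k_sum = np.arange(2, 2 * ng_total + 1, dtype=float)
    p_sum = np.zeros(2 * ng_total - 1)
    np.add.at(p_sum, (ii + jj).astype(int) - 2, p)

    diff_avg = float(np.sum(k_diff * p_diff))
    out: dict[str, float] = {}
    out["Autocorrelation"] = float(np.sum(p * ii * jj))
    out["JointAverage"] = mu_x
    out["ClusterProminence"] = float(np.sum(p * (ii + jj - mu_x - mu_y) ** 4))
    out["ClusterShade"] = float(np.sum(p * (ii + jj - mu_x - mu_y) ** 3))
    out["ClusterTendency"] = float(np.sum(p * (ii + jj - mu_x - mu_y) ** 2))
    out["Contrast"] = float(np.sum(p * (ii - jj) ** 2))
    if sig_x > 0 and sig_y > 0:
        out["Correlation"] = float(
            (np.sum(p * ii * jj) - mu_x * mu_y) / (sig_x * sig_y)
        )
    else:
        out["Correlation"] = 0.0
    out["DifferenceAverage"] = diff_avg
    out["DifferenceEntropy"] = _entropy(p_diff)
    out["DifferenceVariance"] = float(np.sum(p_diff * (k_diff - diff_avg) ** 2))
    out["Id"] = float(np.sum(p / (1.0 + np.abs(ii - jj))))
    out["Idm"] = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    out["Idmn"] = float(np.sum(p / (1.0 + ((ii - jj) ** 2) / ng**2)))
    out["Idn"] = float(np.sum(p / (1.0 + np.abs(ii - jj) / ng)))
    off_diag = ii != jj
    out["InverseVariance"] = float(
        np.sum(p[off_diag] / (ii[off_diag] - jj[off_diag]) ** 2)
    )
    out["JointEnergy"] = float(np.sum(p**2))
    hxy = _entropy(p.ravel())
    out["JointEntropy"] = hxy
    hx = _entropy(px)
    hy = _entropy(py)
    # HXY1 / HXY2 over cells with positive marginal product
    pxy = np.outer(px, py)
    pos = pxy > 0
    hxy1 = float(-np.sum(p[pos] * np.log2(pxy[pos]))) if pos.any() else 0.0
    hxy2 = float(-np.sum(pxy[pos] * np.log2(pxy[pos]))) if pos.any() else 0.0
    div = max(hx, hy)
    out["Imc1"] = float((hxy - hxy1) / div) if div > 0 else 0.0
    out["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if ng > 1 else 0.0
    out["MCC"] = _glcm_mcc(p, px, py, present)
    out["MaximumProbability"] = float(p.max())
    out["SumAverage"] = float(np.sum(k_sum * p_sum))
    out["SumEntropy"] = _entropy(p_sum)
    out["SumSquares"] = float(np.sum(p * (ii - mu_x) ** 2))
    return out


def _glcm_mcc(
    p: np.ndarray, px: np.ndarray, py: np.ndarray, present: np.ndarray
) -> float:
    """Maximal correlation coefficient: sqrt of the second-largest
    eigenvalue of Q(i, j) = sum_k p(i,k) p(j,k) / (px(i) py(k))."""
    idx = np.nonzero(present)[0]
    if idx.size < 2:
        return 0.0
    sub = p[np.ix_(idx, idx)]
    px_s = px[idx]
    py_s = py[idx]
    # Q[a, b] = sum_k sub[a, k] * sub[b, k] / (px_s[a] * py_s[k])
    q = (sub / py_s[np.newaxis, :]) @ sub.T / px_s[:, np.newaxis]
    eig = np.linalg.eigvals(q)
    eig = np.sort(eig.real)
    return float(np.sqrt(max(0.0, eig[-2])))


def glcm_features(
    roi: DiscretizedRoi, matrices: list[np.ndarray] | None = None
) -> dict[str, float]:
    """GLCM features averaged over the 13 directions."""
    if matrices is None:
        matrices = glcm_matrices(roi)
    per_dir = [
        _glcm_single(m) for m in matrices if m.sum() > 0
    ]
    if not per_dir:
        return {f"original_glcm_{n}": 0.0 for n in GLCM_FEATURES}
    return {
        f"original_glcm_{n}": float(np.mean([d[n] for d in per_dir]))
        for n in GLCM_FEATURES
    }


def _size_family(counts: np.ndarray, n_voxels: int, kind: str) -> dict[str, float]:
    """Shared formulas for the run-length / size-zone / dependence families.

    ``counts`` rows are grey levels 1..Ng, columns are sizes (run length,
    zone size or dependence size) 1..Smax; ``kind`` selects the naming.
    """
    ns = counts.sum()
    if ns == 0:
        return {}
    i_vals = np.arange(1, counts.shape[0] + 1, dtype=float)
    j_vals = np.arange(1, counts.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i_vals, j_vals, indexing="ij")
    p = counts / ns
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    mu_i = float(np.sum(p * ii))
    mu_j = float(np.sum(p * jj))

    small = float(np.sum(counts / jj**2) / ns)
    large = float(np.sum(counts * jj**2) / ns)
    low = float(np.sum(counts / ii**2) / ns)
    high = float(np.sum(counts * ii**2) / ns)
    small_low = float(np.sum(counts / (ii**2 * jj**2)) / ns)
    small_high = float(np.sum(counts * ii**2 / jj**2) / ns)
    large_low = float(np.sum(counts * jj**2 / ii**2) / ns)
    large_high = float(np.sum(counts * ii**2 * jj**2) / ns)
    gln = float(np.sum(row**2) / ns)
    glnn = float(np.sum(row**2) / ns**2)
    sn = float(np.sum(col**2) / ns)
    snn = float(np.sum(col**2) / ns**2)
    glv = float(np.sum(p * (ii - mu_i) ** 2))
    sv = float(np.sum(p * (jj - mu_j) ** 2))
    ent = _entropy(p.ravel())
    pct = float(ns / n_voxels)

    if kind == "glrlm":
        return {
            "GrayLevelNonUniformity": gln,
            "GrayLevelNonUniformityNormalized": glnn,
            "GrayLevelVariance": glv,
            "HighGrayLevelRunEmphasis": high,
            "LongRunEmphasis": large,
            "LongRunHighGrayLevelEmphasis": large_high,
            "LongRunLowGrayLevelEmphasis": large_low,
            "LowGrayLevelRunEmphasis": low,
            "RunEntropy": ent,
            "RunLengthNonUniformity": sn,
            "RunLengthNonUniformityNormalized": snn,
            "RunPercentage": pct,
            "RunVariance": sv,
            "ShortRunEmphasis": small,
            "ShortRunHighGrayLevelEmphasis": small_high,
            "ShortRunLowGrayLevelEmphasis": small_low,
        }
    if kind == "glszm":
        return {
            "GrayLevelNonUniformity": gln,
            "GrayLevelNonUniformityNormalized": glnn,
            "GrayLevelVariance": glv,
            "HighGrayLevelZoneEmphasis": high,
            "LargeAreaEmphasis": large,
            "LargeAreaHighGrayLevelEmphasis": large_high,
            "LargeAreaLowGrayLevelEmphasis": large_low,
            "LowGrayLevelZoneEmphasis": low,
            "SizeZoneNonUniformity": sn,
            "SizeZoneNonUniformityNormalized": snn,
            "SmallAreaEmphasis": small,
            "SmallAreaHighGrayLevelEmphasis": small_high,
            "SmallAreaLowGrayLevelEmphasis": small_low,
            "ZoneEntropy": ent,
            "ZonePercentage": pct,
            "ZoneVariance": sv,
        }
    if kind == "gldm":
        return {
            "DependenceEntropy": ent,
            "DependenceNonUniformity": sn,
            "DependenceNonUniformityNormalized": snn,
            "DependenceVariance": sv,
            "GrayLevelNonUniformity": gln,
            "GrayLevelVariance": glv,
            "HighGrayLevelEmphasis": high,
            "LargeDependenceEmphasis": large,
            "LargeDependenceHighGrayLevelEmphasis": large_high,
            "LargeDependenceLowGrayLevelEmphasis": large_low,
            "LowGrayLevelEmphasis": low,
            "SmallDependenceEmphasis": small,
            "SmallDependenceHighGrayLevelEmphasis": small_high,
            "SmallDependenceLowGrayLevelEmphasis": small_low,
        }
    raise ValueError(kind)


def glrlm_features(
    roi: DiscretizedRoi, matrices: list[np.ndarray] | None = None
) -> dict[str, float]:
    """GLRLM features, per-direction values averaged over 13 directions."""
    if matrices is None:
        matrices = glrlm_matrices(roi)
    n_voxels = roi.voxel_count
    per_dir = [
        _size_family(m, n_voxels, "glrlm") for m in matrices if m.sum() > 0
    ]
    per_dir = [d for d in per_dir if d]
    if not per_dir:
        return {f"original_glrlm_{n}": 0.0 for n in GLRLM_FEATURES}
    return {
        f"original_glrlm_{n}": float(np.mean([d[n] for d in per_dir]))
        for n in GLRLM_FEATURES
    }


def glszm_features(
    roi: DiscretizedRoi, matrix: np.ndarray | None = None
) -> dict[str, float]:
    if matrix is None:
        matrix = glszm_matrix(roi)
    vals = _size_family(matrix, roi.voxel_count, "glszm")
    return {f"original_glszm_{n}": vals.get(n, 0.0) for n in GLSZM_FEATURES}


def gldm_features(
    roi: DiscretizedRoi, matrix: np.ndarray | None = None, alpha: int = 0
) -> dict[str, float]:
    if matrix is None:
        matrix = gldm_matrix(roi, alpha=alpha)
    vals = _size_family(matrix, roi.voxel_count, "gldm")
    return {f"original_gldm_{n}": vals.get(n, 0.0) for n in GLDM_FEATURES}


def ngtdm_features(
    roi: DiscretizedRoi, table: dict[str, np.ndarray] | None = None
) -> dict[str, float]:
    if table is None:
        table = ngtdm_table(roi)
    n, p, s = table["n"], table["p"], table["s"]
    n_valid = table["n_valid"]
    i_vals = np.arange(1, p.size + 1, dtype=float)
    present = p > 0
    ngp = int(present.sum())

    out = {name: 0.0 for name in NGTDM_FEATURES}
    if n_valid == 0:
        return {f"original_ngtdm_{k}": v for k, v in out.items()}

    ps = float(np.sum(p * s))
    # Coarseness: reciprocal of sum(p_i * s_i); capped when uniform
    out["Coarseness"] = float(1.0 / ps) if ps > 0 else 1e6

    if ngp > 1:
        ii, jj = np.meshgrid(i_vals, i_vals, indexing="ij")
        pi, pj = np.meshgrid(p, p, indexing="ij")
        both = (pi > 0) & (pj > 0)
        out["Contrast"] = float(
            np.sum(pi[both] * pj[both] * (ii[both] - jj[both]) ** 2)
            / (ngp * (ngp - 1))
            * np.sum(s)
            / n_valid
        )
        denom = float(
            np.sum(np.abs(ii[both] * pi[both] - jj[both] * pj[both]))
        )
        out["Busyness"] = float(ps / denom) if denom > 0 else 0.0
        si, sj = np.meshgrid(s, s, indexing="ij")
        out["Complexity"] = float(
            np.sum(
                np.abs(ii[both] - jj[both])
                * (pi[both] * si[both] + pj[both] * sj[both])
                / (pi[both] + pj[both])
            )
            / n_valid
        )
        ssum = float(np.sum(s))
        out["Strength"] = (
            float(np.sum((pi[both] + pj[both]) * (ii[both] - jj[both]) ** 2) / ssum)
            if ssum > 0
            else 0.0
        )
    return {f"original_ngtdm_{k}": float(v) for k, v in out.items()}
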