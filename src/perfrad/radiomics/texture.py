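"""Texture features from gray-level matrices.

Feature definitions follow the common reference formulary (log base 2).
GLCM and GLRLM features are computed per direction and averaged
("averaged" aggregation; the matrices carry per-direction stacks).
Degenerate inputs (a single gray level, a single run/zone) return the
documented constants rather than NaN: GLCM correlation falls back to 1,
the information measures to 0, NGTDM contrast/busyness/strength to 0 and
coarseness to 1e6 when their denominators vanish.
"""

from __future__ import annotations

import numpy as np

from perfrad.radiomics.matrices import TextureMatrix

_EPS = np.finfo(float).eps
COARSENESS_CAP = 1e6


def _xlog2(p):
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


# --- GLCM -----------------------------------------------------------------

def glcm_features(tm: TextureMatrix) -> dict:
    stack = tm.matrix.astype(float)  # (D, Ng, Ng)
    ng = tm.n_levels
    i = np.arange(1, ng + 1)
    ii = i[None, :, None].astype(float)
    jj = i[None, None, :].astype(float)
    totals = stack.sum(axis=(1, 2), keepdims=True)
    p = stack / np.maximum(totals, _EPS)

    mu_x = (p * ii).sum(axis=(1, 2))  # == mu_y (symmetric matrix)
    sig2 = (p * (ii - mu_x[:, None, None]) ** 2).sum(axis=(1, 2))
    sig = np.sqrt(sig2)

    # marginal and diagonal distributions
    px = p.sum(axis=2)                       # (D, Ng)
    py = p.sum(axis=1)
    d = len(stack)
    k_sum = np.arange(2, 2 * ng + 1)
    k_diff = np.arange(0, ng)
    p_sum = np.zeros((d, k_sum.size))
    p_diff = np.zeros((d, k_diff.size))
    for a in range(ng):
        for b in range(ng):
            p_sum[:, a + b] += p[:, a, b]
            p_diff[:, abs(a - b)] += p[:, a, b]

    contrast = (p * (ii - jj) ** 2).sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (p * (ii - mu_x[:, None, None]) * (jj - mu_x[:, None, None])).sum(axis=(1, 2)) / np.maximum(sig2, _EPS)
    corr = np.where(sig2 > 0, corr, 1.0)  # single level: perfectly correlated

    diff_avg = (p_diff * k_diff).sum(axis=1)
    diff_var = (p_diff * (k_diff - diff_avg[:, None]) ** 2).sum(axis=1)
    diff_ent = -_xlog2(p_diff).sum(axis=1)
    sum_avg = (p_sum * k_sum).sum(axis=1)
    sum_ent = -_xlog2(p_sum).sum(axis=1)

    hxy = -_xlog2(p).sum(axis=(1, 2))
    hx = -_xlog2(px).sum(axis=1)
    pxpy = px[:, :, None] * py[:, None, :]
    hxy1 = -(p * np.log2(np.maximum(pxpy, _EPS)) * (p > 0)).sum(axis=(1, 2))
    hxy2 = -_xlog2(pxpy).sum(axis=(1, 2))
    denom = np.maximum(hx, _EPS)  # hx == hy by symmetry
    imc1 = np.where(hx > 0, (hxy - hxy1) / denom, 0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0, None))

    absdiff = np.abs(ii - jj)
    idm = (p / (1.0 + (ii - jj) ** 2)).sum(axis=(1, 2))
    idmn = (p / (1.0 + ((ii - jj) / ng) ** 2)).sum(axis=(1, 2))
    id_ = (p / (1.0 + absdiff)).sum(axis=(1, 2))
    idn = (p / (1.0 + absdiff / ng)).sum(axis=(1, 2))
    off_diag = absdiff > 0
    inv_var = (np.where(off_diag, p, 0.0) / np.maximum((ii - jj) ** 2, _EPS)).sum(axis=(1, 2))

    feats = {
        "Autocorrelation": (p * ii * jj).sum(axis=(1, 2)),
        "JointAverage": mu_x,
        "ClusterProminence": (p * (ii + jj - 2 * mu_x[:, None, None]) ** 4).sum(axis=(1, 2)),
        "ClusterShade": (p * (ii + jj - 2 * mu_x[:, None, None]) ** 3).sum(axis=(1, 2)),
        "ClusterTendency": (p * (ii + jj - 2 * mu_x[:, None, None]) ** 2).sum(axis=(1, 2)),
        "Contrast": contrast,
        "Correlation": corr,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": diff_ent,
        "DifferenceVariance": diff_var,
        "JointEnergy": (p ** 2).sum(axis=(1, 2)),
        "JointEntropy": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": idm,
        "Idmn": idmn,
        "Id": id_,
        "Idn": idn,
        "InverseVariance": inv_var,
        "MaximumProbability": p.max(axis=(1, 2)),
        "SumAverage": sum_avg,
        "SumEntropy": sum_ent,
        "SumSquares": sig2,
    }
    return {k: float(v.mean()) for k, v in feats.items()}


# --- run-length / size-zone shared forms ----------------------------------

def _rl_family(stack: np.ndarray, n_voxels: int, prefix_small: str, prefix_large: str, kind: str) -> dict:
    """Shared emphasis/nonuniformity forms for GLRLM (per-direction stack)
    and GLSZM/GLDM (single matrix promoted to a stack of one)."""
    if stack.ndim == 2:
        stack = stack[None]
    stack = stack.astype(float)
    d, ng, nl = stack.shape
    i = np.arange(1, ng + 1, dtype=float)[None, :, None]
    j = np.arange(1, nl + 1, dtype=float)[None, None, :]
    n = stack.sum(axis=(1, 2))
    n = np.maximum(n, _EPS)
    p = stack / n[:, None, None]

    mu_i = (p * i).sum(axis=(1, 2))
    mu_j = (p * j).sum(axis=(1, 2))
    feats = {
        f"{prefix_small}Emphasis": (stack / j ** 2).sum(axis=(1, 2)) / n,
        f"{prefix_large}Emphasis": (stack * j ** 2).sum(axis=(1, 2)) / n,
        "GrayLevelNonUniformity": (stack.sum(axis=2) ** 2).sum(axis=1) / n,
        "GrayLevelNonUniformityNormalized": (stack.sum(axis=2) ** 2).sum(axis=1) / n ** 2,
        f"{kind}NonUniformity": (stack.sum(axis=1) ** 2).sum(axis=1) / n,
        f"{kind}NonUniformityNormalized": (stack.sum(axis=1) ** 2).sum(axis=1) / n ** 2,
        "GrayLevelVariance": (p * (i - mu_i[:, None, None]) ** 2).sum(axis=(1, 2)),
        f"{kind}Variance": (p * (j - mu_j[:, None, None]) ** 2).sum(axis=(1, 2)),
        f"{kind}Entropy": -_xlog2(p).sum(axis=(1, 2)),
        "LowGrayLevelEmphasis": (stack / i ** 2).sum(axis=(1, 2)) / n,
        "HighGrayLevelEmphasis": (stack * i ** 2).sum(axis=(1, 2)) / n,
        f"{prefix_small}LowGrayLevelEmphasis": (stack / (i ** 2 * j ** 2)).sum(axis=(1, 2)) / n,
        f"{prefix_small}HighGrayLevelEmphasis": (stack * i ** 2 / j ** 2).sum(axis=(1, 2)) / n,
        f"{prefix_large}LowGrayLevelEmphasis": (stack * j ** 2 / i ** 2).sum(axis=(1, 2)) / n,
        f"{prefix_large}HighGrayLevelEmphasis": (stack * i ** 2 * j ** 2).sum(axis=(1, 2)) / n,
        "_percentage": stack.sum(axis=(1, 2)) / n_voxels,
    }
    return {k: float(v.mean()) for k, v in feats.items()}


def glrlm_features(tm: TextureMatrix) -> dict:
    f = _rl_family(tm.matrix, tm.n_voxels, "ShortRun", "LongRun", "RunLength")
    f["RunPercentage"] = f.pop("_percentage")
    f["RunEntropy"] = f.pop("RunLengthEntropy")
    f["RunVariance"] = f.pop("RunLengthVariance")
    f["LowGrayLevelRunEmphasis"] = f.pop("LowGrayLevelEmphasis")
    f["HighGrayLevelRunEmphasis"] = f.pop("HighGrayLevelEmphasis")
    return f


def glszm_features(tm: TextureMatrix) -> dict:
    f = _rl_family(tm.matrix, tm.n_voxels, "SmallArea", "LargeArea", "SizeZone")
    f["ZonePercentage"] = f.pop("_percentage")
    f["ZoneEntropy"] = f.pop("SizeZoneEntropy")
    f["ZoneVariance"] = f.pop("SizeZoneVariance")
    f["LowGrayLevelZoneEmphasis"] = f.pop("LowGrayLevelEmphasis")
    f["HighGrayLevelZoneEmphasis"] = f.pop("HighGrayLevelEmphasis")
    return f


def gldm_features(tm: TextureMatrix) -> dict:
    f = _rl_family(tm.matrix, tm.n_voxels, "SmallDependence", "LargeDependence", "Dependence")
    del f["_percentage"]  # dependence counts every voxel; percentage is 1
    return f


# --- NGTDM ----------------------------------------------------------------

def ngtdm_features(tm: TextureMatrix) -> dict:
    n_i, s_i = tm.matrix
    ng = tm.n_levels
    i = np.arange(1, ng + 1, dtype=float)
    nvp = n_i.sum()
    if nvp == 0:
        return {k: 0.0 for k in ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")}
    p_i = n_i / nvp
    present = p_i > 0
    ngp = int(present.sum())

    denom_coarse = (p_i * s_i).sum()
    coarseness = float(1.0 / denom_coarse) if denom_coarse > 0 else COARSENESS_CAP

    if ngp > 1:
        pij = p_i[:, None] * p_i[None, :]
        diff2 = (i[:, None] - i[None, :]) ** 2
        contrast = float(pij[np.ix_(present, present)].ravel() @ diff2[np.ix_(present, present)].ravel()
                         / (ngp * (ngp - 1)) * (s_i.sum() / nvp))
    else:
        contrast = 0.0

    ipi = i * p_i
    busy_den = np.abs(ipi[present][:, None] - ipi[present][None, :]).sum()
    busyness = float(denom_coarse / busy_den) if busy_den > 0 else 0.0

    complexity = 0.0
    if ngp > 0:
        ii_, jj_ = np.meshgrid(np.where(present)[0], np.where(present)[0], indexing="ij")
        num = np.abs(i[ii_] - i[jj_]) * (p_i[ii_] * s_i[ii_] + p_i[jj_] * s_i[jj_])
        den = p_i[ii_] + p_i[jj_]
        complexity = float((num / den).sum() / nvp)

    s_sum = s_i.sum()
    if s_sum > 0 and ngp > 1:
        strength = float((((p_i[ii_] + p_i[jj_]) * (i[ii_] - i[jj_]) ** 2).sum()) / s_sum)
    else:
        strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


_FAMILY_FEATURES = {
    "GLCM": glcm_features,
    "GLRLM": glrlm_features,
    "GLSZM": glszm_features,
    "GLDM": gldm_features,
    "NGTDM": ngtdm_features,
}


def texture_features(tm: TextureMatrix) -> dict:
    """Dispatch to the family's feature set; every value is finite."""
    feats = _FAMILY_FEATURES[tm.family](tm)
    for k, v in feats.items():
        if not np.isfinite(v):
            raise AssertionError(f"non-finite feature {tm.family}.{k}")
    return feats
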