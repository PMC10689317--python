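"""Texture-matrix feature families on a quantized ROI.

All four families use the full 3-D neighborhood: 26-connectivity for
zones/dependence/neighborhood-tone statistics and the 13 unique direction
classes at distance 1 for co-occurrence.  When the quantized array has a
singleton axis (a single slice) the neighborhood degenerates to the 2-D
8-neighborhood / 4 directions automatically.

GLCM features are computed per direction on the symmetric normalized
matrix and averaged over directions (IBSI aggregation "by slice-less
averaging over directions").
"""

from __future__ import annotations

import itertools

import numpy as np
from skimage.measure import label as cc_label

from radsurv.features.quantize import QuantizedROI

_EPS = np.finfo(float).eps


def neighbor_offsets(shape) -> list[tuple[int, int, int]]:
    """All 26 neighbor offsets, restricted to axes of extent > 1."""
    ranges = [(-1, 0, 1) if s > 1 else (0,) for s in shape]
    return [o for o in itertools.product(*ranges) if o != (0, 0, 0)]


def direction_offsets(shape) -> list[tuple[int, int, int]]:
    """The 13 unique direction classes (half of the 26 offsets)."""
    offs = neighbor_offsets(shape)
    return [o for o in offs if o > tuple(-c for c in o)]


def _shifted_pairs(levels: np.ndarray, mask: np.ndarray, off):
    """Index pairs (level_a, level_b) of in-ROI voxels separated by ``off``."""
    sl_a, sl_b = [], []
    for o, s in zip(off, levels.shape):
        if o == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif o > 0:
            sl_a.append(slice(0, s - o))
            sl_b.append(slice(o, s))
        else:
            sl_a.append(slice(-o, s))
            sl_b.append(slice(0, s + o))
    a = levels[tuple(sl_a)]
    b = levels[tuple(sl_b)]
    ok = mask[tuple(sl_a)] & mask[tuple(sl_b)]
    return a[ok], b[ok]


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _glcm_matrix(q: QuantizedROI, off) -> np.ndarray:
    """Symmetric gray-level co-occurrence counts for one direction."""
    a, b = _shifted_pairs(q.levels, q.mask, off)
    m = np.zeros((q.ng, q.ng), dtype=float)
    np.add.at(m, (a - 1, b - 1), 1.0)
    return m + m.T


def _mcc(p: np.ndarray) -> float:
    """Maximal correlation coefficient: sqrt of the second-largest eigenvalue
    of Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k)).  Defined as 1 when only
    one gray level occurs."""
    px = p.sum(axis=1)
    keep = px > 0
    if keep.sum() <= 1:
        return 1.0
    psub = p[np.ix_(keep, keep)]
    px = psub.sum(axis=1)
    py = psub.sum(axis=0)
    q = (psub / px[:, None]) @ (psub / py[None, :]).T
    ev = np.sort(np.real(np.linalg.eigvals(q)))[::-1]
    lam2 = min(max(ev[1], 0.0), 1.0)
    return float(np.sqrt(lam2))


def _glcm_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float(np.sum(i * px))
    sig2 = float(np.sum((i - mu) ** 2 * px))
    nz = p > 0
    if sig2 > 0:
        corr = float(np.sum(p * (ii - mu) * (jj - mu)) / sig2)
    else:
        corr = 1.0
    return {
        "MCC": _mcc(p),
        "Contrast": float(np.sum(p * (ii - jj) ** 2)),
        "Correlation": corr,
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": float(-np.sum(p[nz] * np.log2(p[nz]))),
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
    }


def glcm_features(q: QuantizedROI) -> dict[str, float]:
    """Gray-level co-occurrence features averaged over the 13 directions."""
    if not q.mask.any():
        raise ValueError("empty ROI")
    per_dir = []
    for off in direction_offsets(q.levels.shape):
        m = _glcm_matrix(q, off)
        tot = m.sum()
        if tot == 0:
            continue
        per_dir.append(_glcm_single(m / tot))
    if not per_dir:
        # single voxel / no co-occurring pairs: degenerate conventions
        return {"MCC": 1.0, "Contrast": 0.0, "Correlation": 1.0,
                "JointEnergy": 1.0, "JointEntropy": 0.0, "Idm": 1.0}
    keys = per_dir[0].keys()
    return {k: float(np.mean([d[k] for d in per_dir])) for k in keys}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def _zones(q: QuantizedROI):
    """Maximal 26-connected equal-level zones: (level, size) per zone."""
    lab = cc_label(q.levels, background=0, connectivity=q.levels.ndim)
    nlab = lab.max()
    if nlab == 0:
        raise ValueError("empty ROI")
    sizes = np.bincount(lab.ravel())[1:]
    lv = np.zeros(nlab + 1, dtype=np.int64)
    lv[lab.ravel()] = q.levels.ravel()
    return lv[1:], sizes


def glszm_features(q: QuantizedROI) -> dict[str, float]:
    """Gray-level size-zone features (includes LAHGLE and GLNN)."""
    lev, size = _zones(q)
    lev = lev.astype(float)
    size = size.astype(float)
    nz = lev.size
    nv = float(q.mask.sum())
    by_level = np.bincount(lev.astype(int))[1:]  # zones per level
    by_size = np.bincount(size.astype(int))[1:]  # zones per size
    gln = float(np.sum(by_level.astype(float) ** 2) / nz)
    szn = float(np.sum(by_size.astype(float) ** 2) / nz)
    mu_i = float(np.mean(lev))
    mu_j = float(np.mean(size))
    return {
        "SmallAreaEmphasis": float(np.mean(1.0 / size**2)),
        "LargeAreaEmphasis": float(np.mean(size**2)),
        "GrayLevelNonUniformity": gln,
        "GLNN": gln / nz,
        "SizeZoneNonUniformity": szn,
        "SizeZoneNonUniformityNormalized": szn / nz,
        "ZonePercentage": nz / nv,
        "LowGrayLevelZoneEmphasis": float(np.mean(1.0 / lev**2)),
        "HighGrayLevelZoneEmphasis": float(np.mean(lev**2)),
        "SmallAreaLowGrayLevelEmphasis": float(np.mean(1.0 / (lev**2 * size**2))),
        "SmallAreaHighGrayLevelEmphasis": float(np.mean(lev**2 / size**2)),
        "LargeAreaLowGrayLevelEmphasis": float(np.mean(size**2 / lev**2)),
        "LAHGLE": float(np.mean(lev**2 * size**2)),
        "GrayLevelVariance": float(np.mean((lev - mu_i) ** 2)),
        "ZoneVariance": float(np.mean((size - mu_j) ** 2)),
    }


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def _dependence(q: QuantizedROI, alpha: int = 0) -> np.ndarray:
    """Per in-ROI voxel: 1 + number of in-ROI neighbors within alpha levels."""
    dep = np.ones(q.levels.shape, dtype=np.int64)
    for off in neighbor_offsets(q.levels.shape):
        sl_a, sl_b = [], []
        for o, s in zip(off, q.levels.shape):
            if o == 0:
                sl_a.append(slice(None)); sl_b.append(slice(None))
            elif o > 0:
                sl_a.append(slice(0, s - o)); sl_b.append(slice(o, s))
            else:
                sl_a.append(slice(-o, s)); sl_b.append(slice(0, s + o))
        sa, sb = tuple(sl_a), tuple(sl_b)
        ok = (q.mask[sa] & q.mask[sb]
              & (np.abs(q.levels[sa] - q.levels[sb]) <= alpha))
        dep[sa] += ok
    return dep[q.mask]


def gldm_features(q: QuantizedROI, alpha: int = 0) -> dict[str, float]:
    """Gray-level dependence features (includes LDHGLE)."""
    if not q.mask.any():
        raise ValueError("empty ROI")
    lev = q.roi_levels.astype(float)
    dep = _dependence(q, alpha).astype(float)
    nv = lev.size
    by_level = np.bincount(lev.astype(int))[1:].astype(float)
    by_dep = np.bincount(dep.astype(int))[1:].astype(float)
    dn = float(np.sum(by_dep**2) / nv)
    mu_i = float(np.mean(lev))
    mu_j = float(np.mean(dep))
    p_dep = by_dep[by_dep > 0] / nv
    # joint (level, dependence) probabilities for the entropy
    pair = np.bincount((lev.astype(int) - 1) * int(dep.max()) + dep.astype(int) - 1)
    ppair = pair[pair > 0] / nv
    return {
        "SmallDependenceEmphasis": float(np.mean(1.0 / dep**2)),
        "LargeDependenceEmphasis": float(np.mean(dep**2)),
        "GrayLevelNonUniformity": float(np.sum(by_level**2) / nv),
        "DependenceNonUniformity": dn,
        "DependenceNonUniformityNormalized": dn / nv,
        "LowGrayLevelEmphasis": float(np.mean(1.0 / lev**2)),
        "HighGrayLevelEmphasis": float(np.mean(lev**2)),
        "SmallDependenceHighGrayLevelEmphasis": float(np.mean(lev**2 / dep**2)),
        "LargeDependenceLowGrayLevelEmphasis": float(np.mean(dep**2 / lev**2)),
        "LDHGLE": float(np.mean(lev**2 * dep**2)),
        "GrayLevelVariance": float(np.mean((lev - mu_i) ** 2)),
        "DependenceVariance": float(np.mean((dep - mu_j) ** 2)),
        "DependenceEntropy": float(-np.sum(ppair * np.log2(ppair))),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def _ngtdm_table(q: QuantizedROI):
    """Return (n_i, s_i) for levels 1..ng over voxels with >= 1 in-ROI neighbor."""
    shp = q.levels.shape
    nb_sum = np.zeros(shp, dtype=float)
    nb_cnt = np.zeros(shp, dtype=float)
    for off in neighbor_offsets(shp):
        sl_a, sl_b = [], []
        for o, s in zip(off, shp):
            if o == 0:
                sl_a.append(slice(None)); sl_b.append(slice(None))
            elif o > 0:
                sl_a.append(slice(0, s - o)); sl_b.append(slice(o, s))
            else:
                sl_a.append(slice(-o, s)); sl_b.append(slice(0, s + o))
        sa, sb = tuple(sl_a), tuple(sl_b)
        w = q.mask[sb].astype(float)
        nb_sum[sa] += q.levels[sb] * w
        nb_cnt[sa] += w
    valid = q.mask & (nb_cnt > 0)
    lev = q.levels[valid]
    abar = nb_sum[valid] / nb_cnt[valid]
    n_i = np.bincount(lev, minlength=q.ng + 1)[1:].astype(float)
    s_i = np.zeros(q.ng)
    np.add.at(s_i, lev - 1, np.abs(lev - abar))
    return n_i, s_i


def ngtdm_features(q: QuantizedROI) -> dict[str, float]:
    """Neighborhood gray-tone difference features (includes Complexity)."""
    if not q.mask.any():
        raise ValueError("empty ROI")
    n_i, s_i = _ngtdm_table(q)
    nvc = n_i.sum()
    if nvc == 0:
        raise ValueError("no voxel has an in-ROI neighbor")
    p_i = n_i / nvc
    i = np.arange(1, q.ng + 1, dtype=float)
    present = p_i > 0
    ngp = int(present.sum())

    ip, pp, sp = i[present], p_i[present], s_i[present]
    di = np.abs(ip[:, None] - ip[None, :])

    coarse_den = float(np.sum(pp * sp))
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if ngp > 1:
        contrast = (float(np.sum(pp[:, None] * pp[None, :] * di**2))
                    / (ngp * (ngp - 1))) * (float(sp.sum()) / nvc)
        busy_den = float(np.sum(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :])))
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        num = (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
        complexity = float(np.sum(di * num / (pp[:, None] + pp[None, :]))) / nvc
        strength_den = float(sp.sum())
        strength = (float(np.sum((pp[:, None] + pp[None, :]) * di**2)) / strength_den
                    if strength_den > 0 else 0.0)
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }
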