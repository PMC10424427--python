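"""2D texture features: co-occurrence (GLCM), run-length (GLRLM), size-zone
(GLSZM), dependence (GLDM) and neighbourhood grey-tone difference (NGTDM).

Intensities in the region are discretised with a fixed bin width (default
25 HU) relative to the region minimum.  Matrices are built per axial slice;
directional matrices (GLCM, GLRLM) are merged across the four in-plane
directions, and the resulting feature values are averaged across slices with
enough foreground pixels.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..imaging import BinaryMask, ImageVolume
from .registry import TEXTURE_FEATURES

_EPS = np.finfo(float).eps

# in-plane offsets (dx, dy): 0°, 45°, 90°, 135°
_DIRECTIONS_2D = ((1, 0), (1, 1), (0, 1), (-1, 1))


def discretize(
    image: ImageVolume, mask: BinaryMask, bin_width: float = 25.0
) -> np.ndarray:
    """Integer level volume: 0 outside the mask, 1..Ng inside."""
    levels = np.zeros(image.values.shape, dtype=int)
    vals = image.values[mask.values]
    levels[mask.values] = np.floor((vals - vals.min()) / bin_width).astype(int) + 1
    return levels


# ---------------------------------------------------------------------------
# GLCM


def _glcm_matrix(slice_levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts merged over the four 2D directions."""
    p = np.zeros((n_levels, n_levels), dtype=float)
    a = slice_levels
    for dx, dy in _DIRECTIONS_2D:
        sx = slice(max(dx, 0), a.shape[0] + min(dx, 0))
        sy = slice(max(dy, 0), a.shape[1] + min(dy, 0))
        tx = slice(max(-dx, 0), a.shape[0] + min(-dx, 0))
        ty = slice(max(-dy, 0), a.shape[1] + min(-dy, 0))
        src, dst = a[sx, sy], a[tx, ty]
        ok = (src > 0) & (dst > 0)
        np.add.at(p, (src[ok] - 1, dst[ok] - 1), 1.0)
    p = p + p.T
    return p


def _glcm_features(p: np.ndarray) -> dict[str, float]:
    total = p.sum()
    if total == 0:
        raise ValueError("empty co-occurrence matrix")
    p = p / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    k_diff = np.arange(ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])

    da = float((k_diff * p_diff).sum())
    hxy = float(-(p[p > 0] * np.log2(p[p > 0])).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    hy = float(-(py[py > 0] * np.log2(py[py > 0])).sum())
    pxy = np.outer(px, py)
    mask_joint = (pxy > 0)
    hxy1 = float(-(p[mask_joint] * np.log2(pxy[mask_joint] + _EPS)).sum())
    hxy2 = float(-(pxy[mask_joint] * np.log2(pxy[mask_joint] + _EPS)).sum())

    off = ii != jj
    corr = 1.0
    if sig_x > 0 and sig_y > 0:
        corr = float(((ii * jj * p).sum() - mu_x * mu_y) / (sig_x * sig_y))

    imc2_arg = 1.0 - np.exp(-2.0 * max(hxy2 - hxy, 0.0))
    return {
        "glcm_Autocorrelation": float((ii * jj * p).sum()),
        "glcm_JointAverage": mu_x,
        "glcm_ClusterProminence": float(((ii + jj - mu_x - mu_y) ** 4 * p).sum()),
        "glcm_ClusterShade": float(((ii + jj - mu_x - mu_y) ** 3 * p).sum()),
        "glcm_ClusterTendency": float(((ii + jj - mu_x - mu_y) ** 2 * p).sum()),
        "glcm_Contrast": float(((ii - jj) ** 2 * p).sum()),
        "glcm_Correlation": corr,
        "glcm_DifferenceAverage": da,
        "glcm_DifferenceEntropy": float(
            -(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0])).sum()
        ),
        "glcm_DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "glcm_JointEnergy": float((p**2).sum()),
        "glcm_JointEntropy": hxy,
        "glcm_Imc1": float((hxy - hxy1) / max(hx, hy)) if max(hx, hy) > 0 else 0.0,
        "glcm_Imc2": float(np.sqrt(imc2_arg)),
        "glcm_Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "glcm_Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "glcm_Idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "glcm_Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "glcm_InverseVariance": float((p[off] / (ii[off] - jj[off]) ** 2).sum()),
        "glcm_MaximumProbability": float(p.max()),
        "glcm_SumEntropy": float(
            -(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0])).sum()
        ),
        "glcm_SumSquares": float(((ii - mu_x) ** 2 * p).sum()),
    }


# ---------------------------------------------------------------------------
# GLRLM


def _lines(a: np.ndarray, dx: int, dy: int) -> list[np.ndarray]:
    if (dx, dy) == (1, 0):
        return [a[:, j] for j in range(a.shape[1])]
    if (dx, dy) == (0, 1):
        return [a[i, :] for i in range(a.shape[0])]
    if (dx, dy) == (1, 1):
        return [a.diagonal(k) for k in range(-a.shape[0] + 1, a.shape[1])]
    if (dx, dy) == (-1, 1):
        f = np.flipud(a)
        return [f.diagonal(k) for k in range(-f.shape[0] + 1, f.shape[1])]
    raise ValueError((dx, dy))


def _glrlm_matrix(slice_levels: np.ndarray, n_levels: int) -> np.ndarray:
    max_run = max(slice_levels.shape)
    m = np.zeros((n_levels, max_run), dtype=float)
    for dx, dy in _DIRECTIONS_2D:
        for line in _lines(slice_levels, dx, dy):
            if line.size == 0:
                continue
            # split into runs of equal value
            breaks = np.flatnonzero(np.diff(line)) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [line.size]))
            for s, e in zip(starts, ends):
                lev = line[s]
                if lev > 0:
                    m[lev - 1, e - s - 1] += 1.0
    return m


def _glrlm_features(m: np.ndarray, n_pixels: int) -> dict[str, float]:
    nr = m.sum()
    if nr == 0:
        raise ValueError("empty run-length matrix")
    i = np.arange(1, m.shape[0] + 1)[:, None]
    r = np.arange(1, m.shape[1] + 1)[None, :]
    sg = m.sum(axis=1)  # per gray level
    sr = m.sum(axis=0)  # per run length
    p = m / nr
    mu_i = float((i * p).sum())
    mu_r = float((r * p).sum())
    pz = p[p > 0]
    return {
        "glrlm_ShortRunEmphasis": float((m / r**2).sum() / nr),
        "glrlm_LongRunEmphasis": float((m * r**2).sum() / nr),
        "glrlm_GrayLevelNonUniformity": float((sg**2).sum() / nr),
        "glrlm_GrayLevelNonUniformityNormalized": float((sg**2).sum() / nr**2),
        "glrlm_RunLengthNonUniformity": float((sr**2).sum() / nr),
        "glrlm_RunLengthNonUniformityNormalized": float((sr**2).sum() / nr**2),
        "glrlm_RunPercentage": float(nr / (n_pixels * len(_DIRECTIONS_2D))),
        "glrlm_GrayLevelVariance": float(((i - mu_i) ** 2 * p).sum()),
        "glrlm_RunVariance": float(((r - mu_r) ** 2 * p).sum()),
        "glrlm_RunEntropy": float(-(pz * np.log2(pz)).sum()),
        "glrlm_LowGrayLevelRunEmphasis": float((m / i**2).sum() / nr),
        "glrlm_HighGrayLevelRunEmphasis": float((m * i**2).sum() / nr),
        "glrlm_ShortRunLowGrayLevelEmphasis": float((m / (i**2 * r**2)).sum() / nr),
        "glrlm_ShortRunHighGrayLevelEmphasis": float((m * i**2 / r**2).sum() / nr),
        "glrlm_LongRunLowGrayLevelEmphasis": float((m * r**2 / i**2).sum() / nr),
        "glrlm_LongRunHighGrayLevelEmphasis": float((m * i**2 * r**2).sum() / nr),
    }


# ---------------------------------------------------------------------------
# GLSZM

_STRUCT8 = np.ones((3, 3), dtype=int)


def _glszm_matrix(slice_levels: np.ndarray, n_levels: int) -> np.ndarray:
    max_size = int((slice_levels > 0).sum())
    m = np.zeros((n_levels, max_size), dtype=float)
    for lev in np.unique(slice_levels):
        if lev <= 0:
            continue
        lab, nzones = ndimage.label(slice_levels == lev, structure=_STRUCT8)
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            m[lev - 1, s - 1] += 1.0
    return m


def _glszm_features(m: np.ndarray, n_pixels: int) -> dict[str, float]:
    nz = m.sum()
    if nz == 0:
        raise ValueError("empty size-zone matrix")
    i = np.arange(1, m.shape[0] + 1)[:, None]
    s = np.arange(1, m.shape[1] + 1)[None, :]
    sg = m.sum(axis=1)
    ss = m.sum(axis=0)
    p = m / nz
    mu_i = float((i * p).sum())
    mu_s = float((s * p).sum())
    pz = p[p > 0]
    return {
        "glszm_SmallAreaEmphasis": float((m / s**2).sum() / nz),
        "glszm_LargeAreaEmphasis": float((m * s**2).sum() / nz),
        "glszm_GrayLevelNonUniformity": float((sg**2).sum() / nz),
        "glszm_GrayLevelNonUniformityNormalized": float((sg**2).sum() / nz**2),
        "glszm_SizeZoneNonUniformity": float((ss**2).sum() / nz),
        "glszm_SizeZoneNonUniformityNormalized": float((ss**2).sum() / nz**2),
        "glszm_ZonePercentage": float(nz / n_pixels),
        "glszm_GrayLevelVariance": float(((i - mu_i) ** 2 * p).sum()),
        "glszm_ZoneVariance": float(((s - mu_s) ** 2 * p).sum()),
        "glszm_ZoneEntropy": float(-(pz * np.log2(pz)).sum()),
        "glszm_LowGrayLevelZoneEmphasis": float((m / i**2).sum() / nz),
        "glszm_HighGrayLevelZoneEmphasis": float((m * i**2).sum() / nz),
        "glszm_SmallAreaLowGrayLevelEmphasis": float((m / (i**2 * s**2)).sum() / nz),
        "glszm_SmallAreaHighGrayLevelEmphasis": float((m * i**2 / s**2).sum() / nz),
        "glszm_LargeAreaLowGrayLevelEmphasis": float((m * s**2 / i**2).sum() / nz),
        "glszm_LargeAreaHighGrayLevelEmphasis": float((m * i**2 * s**2).sum() / nz),
    }


# ---------------------------------------------------------------------------
# GLDM


def _neighbor_stacks(a: np.ndarray) -> list[np.ndarray]:
    """The 8 neighbour arrays of a 2D array, zero-padded at the border."""
    out = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            shifted = np.zeros_like(a)
            sx = slice(max(dx, 0), a.shape[0] + min(dx, 0))
            sy = slice(max(dy, 0), a.shape[1] + min(dy, 0))
            tx = slice(max(-dx, 0), a.shape[0] + min(-dx, 0))
            ty = slice(max(-dy, 0), a.shape[1] + min(-dy, 0))
            shifted[tx, ty] = a[sx, sy]
            out.append(shifted)
    return out


def _gldm_matrix(slice_levels: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    inside = slice_levels > 0
    neighbors = _neighbor_stacks(slice_levels)
    dep = np.zeros(slice_levels.shape, dtype=int)
    for nb in neighbors:
        dep += ((np.abs(nb - slice_levels) <= alpha) & (nb > 0) & inside).astype(int)
    m = np.zeros((n_levels, 9 + 1), dtype=float)  # dependence j = count+1 in 1..9
    np.add.at(m, (slice_levels[inside] - 1, dep[inside] + 1 - 1), 1.0)
    return m[:, : m.shape[1]]


def _gldm_features(m: np.ndarray) -> dict[str, float]:
    nd = m.sum()
    if nd == 0:
        raise ValueError("empty dependence matrix")
    i = np.arange(1, m.shape[0] + 1)[:, None]
    j = np.arange(1, m.shape[1] + 1)[None, :]
    sg = m.sum(axis=1)
    sd = m.sum(axis=0)
    p = m / nd
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    pz = p[p > 0]
    return {
        "gldm_SmallDependenceEmphasis": float((m / j**2).sum() / nd),
        "gldm_LargeDependenceEmphasis": float((m * j**2).sum() / nd),
        "gldm_GrayLevelNonUniformity": float((sg**2).sum() / nd),
        "gldm_DependenceNonUniformity": float((sd**2).sum() / nd),
        "gldm_DependenceNonUniformityNormalized": float((sd**2).sum() / nd**2),
        "gldm_GrayLevelVariance": float(((i - mu_i) ** 2 * p).sum()),
        "gldm_DependenceVariance": float(((j - mu_j) ** 2 * p).sum()),
        "gldm_DependenceEntropy": float(-(pz * np.log2(pz)).sum()),
        "gldm_LowGrayLevelEmphasis": float((m / i**2).sum() / nd),
        "gldm_HighGrayLevelEmphasis": float((m * i**2).sum() / nd),
        "gldm_SmallDependenceLowGrayLevelEmphasis": float(
            (m / (i**2 * j**2)).sum() / nd
        ),
        "gldm_SmallDependenceHighGrayLevelEmphasis": float(
            (m * i**2 / j**2).sum() / nd
        ),
        "gldm_LargeDependenceLowGrayLevelEmphasis": float(
            (m * j**2 / i**2).sum() / nd
        ),
        "gldm_LargeDependenceHighGrayLevelEmphasis": float(
            (m * i**2 * j**2).sum() / nd
        ),
    }


# ---------------------------------------------------------------------------
# NGTDM


def _ngtdm_features(slice_levels: np.ndarray, n_levels: int) -> dict[str, float]:
    inside = slice_levels > 0
    n_total = int(inside.sum())
    if n_total == 0:
        raise ValueError("empty region")
    neighbors = _neighbor_stacks(slice_levels)
    nb_sum = np.zeros(slice_levels.shape, dtype=float)
    nb_cnt = np.zeros(slice_levels.shape, dtype=int)
    for nb in neighbors:
        valid = nb > 0
        nb_sum += np.where(valid, nb, 0)
        nb_cnt += valid.astype(int)
    has_nb = inside & (nb_cnt > 0)
    diff = np.zeros(slice_levels.shape, dtype=float)
    diff[has_nb] = np.abs(
        slice_levels[has_nb] - nb_sum[has_nb] / nb_cnt[has_nb]
    )

    s = np.zeros(n_levels)
    n_i = np.zeros(n_levels)
    np.add.at(s, slice_levels[has_nb] - 1, diff[has_nb])
    np.add.at(n_i, slice_levels[has_nb] - 1, 1.0)
    n_valid = n_i.sum()
    if n_valid == 0:
        raise ValueError("no valid NGTDM pixels")
    p_i = n_i / n_valid
    present = p_i > 0
    iv = np.arange(1, n_levels + 1, dtype=float)
    ngp = int(present.sum())

    coarse_den = float((p_i * s).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    pi_p, iv_p, s_p = p_i[present], iv[present], s[present]
    dif2 = (iv_p[:, None] - iv_p[None, :]) ** 2
    pp = pi_p[:, None] * pi_p[None, :]
    contrast = 0.0
    if ngp > 1:
        contrast = float((pp * dif2).sum() / (ngp * (ngp - 1)) * s_p.sum() / n_valid)
    busy_den = float(np.abs(iv_p[:, None] * pi_p[:, None] - iv_p[None, :] * pi_p[None, :]).sum())
    busyness = float((pi_p * s_p).sum() / busy_den) if busy_den > 0 else 0.0
    num = np.abs(iv_p[:, None] - iv_p[None, :]) * (
        pi_p[:, None] * s_p[:, None] + pi_p[None, :] * s_p[None, :]
    )
    den = pi_p[:, None] + pi_p[None, :]
    complexity = float((num / den).sum() / n_valid)
    s_sum = float(s_p.sum())
    strength = (
        float(((pi_p[:, None] + pi_p[None, :]) * dif2).sum() / s_sum)
        if s_sum > 0
        else 0.0
    )
    return {
        "ngtdm_Coarseness": float(coarseness),
        "ngtdm_Contrast": contrast,
        "ngtdm_Busyness": busyness,
        "ngtdm_Complexity": complexity,
        "ngtdm_Strength": strength,
    }


# ---------------------------------------------------------------------------


def texture_features(
    image: ImageVolume,
    mask: BinaryMask,
    bin_width: float = 25.0,
    min_pixels_per_slice: int = 5,
) -> dict[str, float]:
    """All 73 texture features for one region, averaged over axial slices."""
    if mask.is_empty:
        raise ValueError("mask is empty")
    levels = discretize(image, mask, bin_width)
    n_levels = int(levels.max())
    per_slice: list[dict[str, float]] = []
    for z in range(levels.shape[2]):
        sl = levels[:, :, z]
        n_px = int((sl > 0).sum())
        if n_px < min_pixels_per_slice:
            continue
        feats: dict[str, float] = {}
        glcm = _glcm_matrix(sl, n_levels)
        if glcm.sum() == 0:
            continue
        feats.update(_glcm_features(glcm))
        feats.update(_glrlm_features(_glrlm_matrix(sl, n_levels), n_px))
        feats.update(_glszm_features(_glszm_matrix(sl, n_levels), n_px))
        feats.update(_gldm_features(_gldm_matrix(sl, n_levels)))
        feats.update(_ngtdm_features(sl, n_levels))
        per_slice.append(feats)
    if not per_slice:
        raise ValueError(
            "no slice has enough foreground pixels for texture features"
        )
    out = {
        name: float(np.mean([f[name] for f in per_slice])) for name in per_slice[0]
    }
    assert set(out) == set(TEXTURE_FEATURES)
    return out
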