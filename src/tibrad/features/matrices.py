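"""Gray-level matrix texture families: GLCM, GLRLM, GLSZM, NGTDM.

All four families operate on a quantized volume restricted to a mask:
intensities are binned to G equal-width levels between the in-mask min and
max, and matrix statistics are accumulated only over in-mask voxels. GLCM
and GLRLM are direction-dependent and are aggregated as mean and SD over the
13 unique 3-D directions; GLSZM (26-connected zones) and NGTDM
(26-neighborhood gray-tone differences) are single 3-D matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: The 13 unique 3-D offsets (one per direction, up to sign).
OFFSETS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_EPS = np.finfo(float).tiny
#: Documented stand-in for NGTDM coarseness when its denominator vanishes.
COARSENESS_CAP = 1.0e6


@dataclass
class QuantizedVolume:
    """Integer levels in [1, G] inside the mask; 0 outside."""

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    vmin: float
    vmax: float


def quantize(volume: np.ndarray, mask: np.ndarray, n_levels: int = 16) -> QuantizedVolume:
    """Equal-width quantization between the in-mask min and max.

    The maximum maps to level G; a constant volume maps every in-mask voxel
    to level 1 (documented convention, not an error).
    """
    if n_levels < 2:
        raise ValueError("need at least 2 gray levels")
    if not mask.any():
        raise ValueError("empty mask")
    vals = volume[mask]
    vmin, vmax = float(vals.min()), float(vals.max())
    levels = np.zeros(volume.shape, dtype=np.int32)
    if vmax > vmin:
        lv = np.floor((volume[mask] - vmin) / (vmax - vmin) * n_levels).astype(np.int32) + 1
        levels[mask] = np.clip(lv, 1, n_levels)
    else:
        levels[mask] = 1
    return QuantizedVolume(levels, mask.astype(bool), n_levels, vmin, vmax)


def _shifted_views(a: np.ndarray, offset: tuple[int, int, int]):
    """Aligned (source, destination) views of ``a`` under ``offset``."""
    src = []
    dst = []
    for n, d in zip(a.shape, offset):
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    return a[tuple(src)], a[tuple(dst)]


# ---------------------------------------------------------------------------
# GLCM


def glcm(q: QuantizedVolume, offset: tuple[int, int, int]) -> np.ndarray:
    """Raw symmetric co-occurrence counts (each pair counted both directions)."""
    if offset == (0, 0, 0):
        raise ValueError("offset must be non-zero")
    m_src, m_dst = _shifted_views(q.mask, offset)
    valid = m_src & m_dst
    if not valid.any():
        raise ValueError("no valid voxel pairs for this offset")
    l_src, l_dst = _shifted_views(q.levels, offset)
    a = l_src[valid] - 1
    b = l_dst[valid] - 1
    counts = np.zeros((q.n_levels, q.n_levels), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    return counts + counts.T


GLCM_FEATURE_NAMES = (
    "contrast",
    "dissimilarity",
    "homogeneity",
    "asm",
    "energy",
    "correlation",
    "entropy",
    "max_probability",
    "cluster_shade",
    "cluster_prominence",
    "autocorrelation",
)


def glcm_features(counts: np.ndarray) -> dict[str, float]:
    """Haralick-style statistics of one normalized co-occurrence matrix."""
    p = counts / counts.sum()
    g = p.shape[0]
    i = np.arange(1, g + 1)[:, None]
    j = np.arange(1, g + 1)[None, :]
    px = p.sum(axis=1)
    mu_x = float((np.arange(1, g + 1) * px).sum())
    mu_y = mu_x  # symmetric matrix
    var_x = float(((np.arange(1, g + 1) - mu_x) ** 2 * px).sum())
    diff = i - j
    feats = {
        "contrast": float((diff**2 * p).sum()),
        "dissimilarity": float((np.abs(diff) * p).sum()),
        "homogeneity": float((p / (1.0 + diff**2)).sum()),
        "asm": float((p**2).sum()),
    }
    feats["energy"] = float(np.sqrt(feats["asm"]))
    if var_x > 0:
        feats["correlation"] = float(((i * j * p).sum() - mu_x * mu_y) / var_x)
    else:
        feats["correlation"] = 0.0  # single-level matrix: undefined, set 0
    nz = p[p > 0]
    feats["entropy"] = float(-(nz * np.log2(nz)).sum())
    feats["max_probability"] = float(p.max())
    feats["cluster_shade"] = float((((i + j) - mu_x - mu_y) ** 3 * p).sum())
    feats["cluster_prominence"] = float((((i + j) - mu_x - mu_y) ** 4 * p).sum())
    feats["autocorrelation"] = float((i * j * p).sum())
    return feats


# ---------------------------------------------------------------------------
# GLRLM


def glrlm(q: QuantizedVolume, direction: tuple[int, int, int]) -> np.ndarray:
    """Run-length matrix: counts of maximal constant-level in-mask runs.

    Entry ``(g-1, L-1)`` counts maximal runs of level ``g`` and length ``L``
    along ``direction``; leaving the mask breaks a run.
    """
    if direction == (0, 0, 0):
        raise ValueError("direction must be non-zero")
    if not q.mask.any():
        raise ValueError("empty mask")
    mask, lv = q.mask, q.levels
    shape = np.array(mask.shape)
    d = np.array(direction)

    # A voxel starts a run if its backward neighbour is out of grid, out of
    # mask, or has a different level.
    m_src, m_dst = _shifted_views(mask, tuple(d))
    l_src, l_dst = _shifted_views(lv, tuple(d))
    cont = np.zeros(mask.shape, dtype=bool)  # voxel continues the run of its predecessor
    cont_view_src = m_src & m_dst & (l_src == l_dst)
    # place into destination-aligned positions
    dst_slices = []
    for n, dd in zip(mask.shape, direction):
        dst_slices.append(slice(dd, n) if dd >= 0 else slice(0, n + dd))
    cont[tuple(dst_slices)] = cont_view_src
    starts = mask & ~cont

    pos = np.argwhere(starts)
    lengths = np.ones(len(pos), dtype=np.int64)
    levels = lv[tuple(pos.T)]
    active = np.arange(len(pos))
    cur = pos.copy()
    while active.size:
        nxt = cur[active] + d
        inb = np.all((nxt >= 0) & (nxt < shape), axis=1)
        ok = np.zeros(active.size, dtype=bool)
        if inb.any():
            ni = nxt[inb]
            idx = tuple(ni.T)
            ok[inb] = mask[idx] & (lv[idx] == levels[active[inb]])
        lengths[active[ok]] += 1
        cur[active[ok]] += d
        active = active[ok]

    max_len = int(lengths.max())
    R = np.zeros((q.n_levels, max_len), dtype=np.int64)
    np.add.at(R, (levels - 1, lengths - 1), 1)
    return R


GLRLM_FEATURE_NAMES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized",
    "run_length_nonuniformity",
    "run_length_nonuniformity_normalized",
    "run_percentage",
    "gray_level_variance",
    "run_length_variance",
    "run_entropy",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
)


def _size_weighted_features(M: np.ndarray, n_voxels: int, prefix: str) -> dict[str, float]:
    """Shared gray-level x size/length statistics for GLRLM and GLSZM.

    ``prefix`` chooses the naming dialect: "run" or (for GLSZM) "zone"/"area".
    """
    n = M.sum()
    p = M / n
    g = np.arange(1, M.shape[0] + 1, dtype=float)[:, None]
    s = np.arange(1, M.shape[1] + 1, dtype=float)[None, :]
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_g = float((g[:, 0] * pg).sum())
    mu_s = float((s[0] * ps).sum())
    nz = p[p > 0]
    small = "short_run" if prefix == "run" else "small_area"
    large = "long_run" if prefix == "run" else "large_area"
    length = "run_length" if prefix == "run" else "zone_size"
    ent = "run_entropy" if prefix == "run" else "zone_entropy"
    pct = "run_percentage" if prefix == "run" else "zone_percentage"
    var_s = "run_length_variance" if prefix == "run" else "zone_size_variance"
    return {
        f"{small}_emphasis": float((p / s**2).sum()),
        f"{large}_emphasis": float((p * s**2).sum()),
        "gray_level_nonuniformity": float((M.sum(axis=1) ** 2).sum() / n),
        "gray_level_nonuniformity_normalized": float((pg**2).sum()),
        f"{length}_nonuniformity": float((M.sum(axis=0) ** 2).sum() / n),
        f"{length}_nonuniformity_normalized": float((ps**2).sum()),
        pct: float(n / n_voxels),
        "gray_level_variance": float(((g - mu_g) ** 2 * p).sum()),
        var_s: float(((s - mu_s) ** 2 * p).sum()),
        ent: float(-(nz * np.log2(nz)).sum()),
        f"low_gray_level_{prefix}_emphasis": float((p / g**2).sum()),
        f"high_gray_level_{prefix}_emphasis": float((p * g**2).sum()),
        f"{small}_low_gray_level_emphasis": float((p / (g**2 * s**2)).sum()),
        f"{small}_high_gray_level_emphasis": float((p * g**2 / s**2).sum()),
        f"{large}_low_gray_level_emphasis": float((p * s**2 / g**2).sum()),
        f"{large}_high_gray_level_emphasis": float((p * g**2 * s**2).sum()),
    }


def glrlm_features(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    feats = _size_weighted_features(R, n_voxels, "run")
    return {k: feats[k] for k in GLRLM_FEATURE_NAMES}


# ---------------------------------------------------------------------------
# GLSZM

GLSZM_FEATURE_NAMES = (
    "small_area_emphasis",
    "large_area_emphasis",
    "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized",
    "zone_size_nonuniformity",
    "zone_size_nonuniformity_normalized",
    "zone_percentage",
    "gray_level_variance",
    "zone_size_variance",
    "zone_entropy",
    "low_gray_level_zone_emphasis",
    "high_gray_level_zone_emphasis",
    "small_area_low_gray_level_emphasis",
    "small_area_high_gray_level_emphasis",
    "large_area_low_gray_level_emphasis",
    "large_area_high_gray_level_emphasis",
)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def glszm(q: QuantizedVolume) -> np.ndarray:
    """Size-zone matrix: 26-connected constant-level zones by size."""
    if not q.mask.any():
        raise ValueError("empty mask")
    n_vox = int(q.mask.sum())
    S = np.zeros((q.n_levels, n_vox), dtype=np.int64)
    max_size = 0
    for g in range(1, q.n_levels + 1):
        binary = (q.levels == g) & q.mask
        if not binary.any():
            continue
        lab, nzones = ndimage.label(binary, structure=_CONN26)
        sizes = np.bincount(lab.ravel())[1:]
        for sz in sizes:
            S[g - 1, sz - 1] += 1
        max_size = max(max_size, int(sizes.max()))
    return S[:, :max_size]


def glszm_features(S: np.ndarray, n_voxels: int) -> dict[str, float]:
    feats = _size_weighted_features(S, n_voxels, "zone")
    return {k: feats[k] for k in GLSZM_FEATURE_NAMES}


# ---------------------------------------------------------------------------
# NGTDM

NGTDM_FEATURE_NAMES = ("coarseness", "contrast", "busyness", "complexity", "strength")


def ngtdm(q: QuantizedVolume) -> tuple[np.ndarray, np.ndarray]:
    """Neighborhood gray-tone difference table.

    Returns ``(n_i, s_i)`` for levels i = 1..G: voxel counts and summed
    absolute differences between each voxel's level and the mean level of its
    in-mask 26-neighborhood (voxels with no in-mask neighbour are excluded).
    """
    if not q.mask.any():
        raise ValueError("empty mask")
    kern = np.ones((3, 3, 3))
    kern[1, 1, 1] = 0.0
    m = q.mask.astype(float)
    neigh_sum = ndimage.correlate(q.levels * m, kern, mode="constant")
    neigh_cnt = ndimage.correlate(m, kern, mode="constant")
    valid = q.mask & (neigh_cnt > 0)
    n = np.zeros(q.n_levels, dtype=np.int64)
    s = np.zeros(q.n_levels, dtype=np.float64)
    lv = q.levels[valid]
    diffs = np.abs(lv - neigh_sum[valid] / neigh_cnt[valid])
    np.add.at(n, lv - 1, 1)
    np.add.at(s, lv - 1, diffs)
    return n, s


def ngtdm_features(n: np.ndarray, s: np.ndarray) -> dict[str, float]:
    """Amadasun-King statistics with documented degenerate-case conventions.

    Zero denominators (e.g. a constant volume) give coarseness = 1e6 and
    busyness/strength = 0, never infinity.
    """
    N = n.sum()
    p = n / N
    present = n > 0
    ngp = int(present.sum())
    i = np.arange(1, len(n) + 1, dtype=float)

    denom = float((p * s).sum())
    coarseness = 1.0 / denom if denom > 0 else COARSENESS_CAP

    if ngp > 1:
        ii = i[present][:, None]
        jj = i[present][None, :]
        pi = p[present][:, None]
        pj = p[present][None, :]
        contrast = float(
            (pi * pj * (ii - jj) ** 2).sum() / (ngp * (ngp - 1)) * (s.sum() / N)
        )
        busy_den = float(np.abs(ii * pi - jj * pj).sum())
        busyness = denom / busy_den if busy_den > 0 else 0.0
        si = s[present][:, None]
        sj = s[present][None, :]
        complexity = float((np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum() / N)
        s_sum = float(s.sum())
        strength = float(((pi + pj) * (ii - jj) ** 2).sum() / s_sum) if s_sum > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }
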