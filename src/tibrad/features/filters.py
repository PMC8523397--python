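"""Slice-wise filter-bank texture families: local binary patterns and Gabor.

Both families are computed on 2-D sagittal slices (constant-x planes) of the
VOI, the plane in which the original bone-texture literature operates, and
summarized over all in-mask pixels of all slices.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
from scipy.signal import fftconvolve
from scipy.stats import kurtosis, skew
from skimage.feature import local_binary_pattern
from skimage.filters import gabor_kernel

DEFAULT_LBP_RADII = (1, 2, 3)
DEFAULT_LBP_POINTS = 8
DEFAULT_GABOR_FREQUENCIES = (0.05, 0.1, 0.2, 0.3, 0.4)
DEFAULT_GABOR_ANGLES_DEG = tuple(180.0 * k / 8 for k in range(8))


def _slices_with_mask(volume: np.ndarray, mask: np.ndarray, axis: int = 0):
    for idx in range(volume.shape[axis]):
        sl = [slice(None)] * 3
        sl[axis] = idx
        m = mask[tuple(sl)]
        if m.any():
            yield volume[tuple(sl)], m


def lbp_features(
    volume: np.ndarray,
    mask: np.ndarray,
    radii: tuple[int, ...] = DEFAULT_LBP_RADII,
    points: int = DEFAULT_LBP_POINTS,
) -> dict[str, float]:
    """Rotation-invariant uniform LBP code statistics per radius.

    Per radius: the fraction of in-mask pixels carrying each of the P+2
    rotation-invariant uniform codes, plus the mean and SD of the code value.
    Pixels closer than the radius to the slice border are excluded (their
    circular neighbourhood is undefined).
    """
    if any(r < 1 for r in radii):
        raise ValueError("LBP radii must be >= 1 voxel")
    rmax = max(radii)
    if volume.shape[1] < 2 * rmax + 1 or volume.shape[2] < 2 * rmax + 1:
        raise ValueError(
            f"VOI in-plane extent {volume.shape[1:]} thinner than 2r+1 = {2 * rmax + 1}"
        )
    n_codes = points + 2
    out: dict[str, float] = {}
    for r in radii:
        codes: list[np.ndarray] = []
        for img, m in _slices_with_mask(volume, mask):
            with warnings.catch_warnings():
                # continuous-valued MRI: exact-equality ties are measure-zero
                warnings.simplefilter("ignore", UserWarning)
                lbp = local_binary_pattern(img.astype(np.float64), points, r, method="uniform")
            valid = np.zeros_like(m)
            valid[r:-r, r:-r] = True
            sel = m & valid
            if sel.any():
                codes.append(lbp[sel])
        if not codes:
            raise ValueError("no in-mask pixels away from slice borders")
        allc = np.concatenate(codes)
        hist = np.bincount(allc.astype(np.int64), minlength=n_codes)[:n_codes]
        frac = hist / hist.sum()
        for c in range(n_codes):
            out[f"lbp_r{r}_code{c}"] = float(frac[c])
        out[f"lbp_r{r}_mean"] = float(allc.mean())
        out[f"lbp_r{r}_sd"] = float(allc.std())
    return out


@lru_cache(maxsize=256)
def _dc_free_gabor_kernel(frequency: float, theta: float) -> np.ndarray:
    """Gabor kernel with its mean removed so constant images give zero response."""
    k = gabor_kernel(frequency, theta=theta)
    return k - k.mean()


def gabor_features(
    volume: np.ndarray,
    mask: np.ndarray,
    frequencies: tuple[float, ...] = DEFAULT_GABOR_FREQUENCIES,
    angles_deg: tuple[float, ...] = DEFAULT_GABOR_ANGLES_DEG,
) -> dict[str, float]:
    """Slice-wise Gabor filter-bank response-magnitude statistics.

    Per (frequency, angle): mean, SD, skewness and kurtosis of the response
    magnitude over in-mask pixels of all sagittal slices. Frequencies are in
    cycles/pixel and must not exceed the Nyquist limit 0.5.
    """
    if not frequencies or not angles_deg:
        raise ValueError("need at least one frequency and one angle")
    for f in frequencies:
        if f > 0.5:
            raise ValueError(f"frequency {f} cycles/pixel exceeds Nyquist (0.5)")
        if f <= 0:
            raise ValueError("frequencies must be positive")
    slices = list(_slices_with_mask(volume, mask))
    if not slices:
        raise ValueError("empty mask")
    out: dict[str, float] = {}
    for f in frequencies:
        for ang in angles_deg:
            kern = _dc_free_gabor_kernel(float(f), float(np.deg2rad(ang)))
            kh, kw = kern.shape
            pads = ((kh // 2, kh - 1 - kh // 2), (kw // 2, kw - 1 - kw // 2))
            mags: list[np.ndarray] = []
            for img, m in slices:
                # edge-replicated padding keeps the DC-free property exact at
                # the slice borders (a truncated kernel is no longer zero-sum)
                padded = np.pad(img.astype(np.float64), pads, mode="edge")
                resp = fftconvolve(padded, kern, mode="valid")
                mags.append(np.abs(resp)[m])
            v = np.concatenate(mags)
            sd = float(v.std())
            tag = f"gabor_f{f:g}_a{ang:g}"
            out[f"{tag}_mean"] = float(v.mean())
            out[f"{tag}_sd"] = sd
            out[f"{tag}_skewness"] = float(skew(v)) if sd > 0 else 0.0
            out[f"{tag}_kurtosis"] = float(kurtosis(v)) if sd > 0 else 0.0
    return out
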