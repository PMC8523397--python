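"""Histogram-based (first-order) intensity statistics."""

from __future__ import annotations

import numpy as np
from scipy.stats import kurtosis, skew

HISTOGRAM_FEATURE_NAMES = (
    "min",
    "max",
    "mean",
    "median",
    "sd",
    "skewness",
    "kurtosis",
    "range",
    "iqr",
    "entropy",
    "energy",
    "peak",
)


def histogram_features(
    volume: np.ndarray, mask: np.ndarray, bins: int = 16
) -> dict[str, float]:
    """The 12 first-order statistics of the in-mask intensity distribution.

    ``entropy`` and ``energy`` (sum of squared bin probabilities, i.e.
    histogram uniformity) use an equal-width histogram with ``bins`` bins;
    ``peak`` is the centre of the modal bin. A zero-variance sample gets
    skewness = kurtosis = 0 by convention.
    """
    vals = volume[mask].astype(np.float64)
    if vals.size < 2:
        raise ValueError("need at least 2 in-mask voxels")
    sd = float(vals.std())
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax > vmin:
        hist, edges = np.histogram(vals, bins=bins, range=(vmin, vmax))
        p = hist / hist.sum()
        nz = p[p > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        energy = float((p**2).sum())
        peak = float((edges[np.argmax(hist)] + edges[np.argmax(hist) + 1]) / 2.0)
    else:
        entropy, energy, peak = 0.0, 1.0, vmin
    q75, q25 = np.percentile(vals, [75, 25])
    return {
        "min": vmin,
        "max": vmax,
        "mean": float(vals.mean()),
        "median": float(np.median(vals)),
        "sd": sd,
        "skewness": float(skew(vals)) if sd > 0 else 0.0,
        "kurtosis": float(kurtosis(vals)) if sd > 0 else 0.0,
        "range": vmax - vmin,
        "iqr": float(q75 - q25),
        "entropy": entropy,
        "energy": energy,
        "peak": peak,
    }
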