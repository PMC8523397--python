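"""Per-VOI feature extraction with pinned family counts.

The extraction configuration is the single source of truth for the feature
itemization: 3 orientation + 12 histogram + 271 texture features per VOI and
17 shape features for the whole tibial volume. The 271 texture features
decompose as GLCM 11x2 (mean/SD over 13 directions) + GLRLM 16x2 + GLSZM 16
+ NGTDM 5 + LBP 3 radii x 12 + Gabor 5 frequencies x 8 angles x 4 statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..core import ImageVolume
from ..voi import VOI_NAMES, VOISet
from .filters import (
    DEFAULT_GABOR_ANGLES_DEG,
    DEFAULT_GABOR_FREQUENCIES,
    DEFAULT_LBP_POINTS,
    DEFAULT_LBP_RADII,
    gabor_features,
    lbp_features,
)
from .firstorder import HISTOGRAM_FEATURE_NAMES, histogram_features
from .matrices import (
    GLCM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    GLSZM_FEATURE_NAMES,
    NGTDM_FEATURE_NAMES,
    OFFSETS_13,
    glcm,
    glcm_features,
    glrlm,
    glrlm_features,
    glszm,
    glszm_features,
    ngtdm,
    ngtdm_features,
    quantize,
)
from .shape import ORIENTATION_FEATURE_NAMES, SHAPE_FEATURE_NAMES, orientation_features, shape_features

FAMILIES = ("shape", "orientation", "histogram", "texture")


@dataclass(frozen=True)
class FeatureConfig:
    """Pinned extraction parameters reproducing the printed family totals."""

    gray_levels: int = 16
    histogram_bins: int = 16
    lbp_radii: tuple[int, ...] = DEFAULT_LBP_RADII
    lbp_points: int = DEFAULT_LBP_POINTS
    gabor_frequencies: tuple[float, ...] = DEFAULT_GABOR_FREQUENCIES
    gabor_angles_deg: tuple[float, ...] = DEFAULT_GABOR_ANGLES_DEG
    expected_counts: dict[str, int] = field(
        default_factory=lambda: {"shape": 17, "orientation": 3, "histogram": 12, "texture": 271}
    )

    def texture_count(self) -> int:
        n_glcm = 2 * len(GLCM_FEATURE_NAMES)
        n_glrlm = 2 * len(GLRLM_FEATURE_NAMES)
        n_glszm = len(GLSZM_FEATURE_NAMES)
        n_ngtdm = len(NGTDM_FEATURE_NAMES)
        n_lbp = len(self.lbp_radii) * (self.lbp_points + 2 + 2)
        n_gabor = len(self.gabor_frequencies) * len(self.gabor_angles_deg) * 4
        return n_glcm + n_glrlm + n_glszm + n_ngtdm + n_lbp + n_gabor

    def validate_counts(self) -> None:
        got = {
            "shape": len(SHAPE_FEATURE_NAMES),
            "orientation": len(ORIENTATION_FEATURE_NAMES),
            "histogram": len(HISTOGRAM_FEATURE_NAMES),
            "texture": self.texture_count(),
        }
        if got != self.expected_counts:
            raise ValueError(f"feature family counts {got} != expected {self.expected_counts}")


def _aggregate_directional(per_dir: list[dict[str, float]], prefix: str) -> dict[str, float]:
    out = {}
    names = per_dir[0].keys()
    for name in names:
        vals = np.array([d[name] for d in per_dir])
        out[f"{prefix}_{name}_mean"] = float(vals.mean())
        out[f"{prefix}_{name}_sd"] = float(vals.std())
    return out


def texture_features(
    volume: np.ndarray, mask: np.ndarray, config: FeatureConfig
) -> dict[str, float]:
    """All texture families for one VOI; names are family_statistic_parameter."""
    q = quantize(volume, mask, config.gray_levels)
    n_vox = int(mask.sum())
    out: dict[str, float] = {}
    out.update(_aggregate_directional([glcm_features(glcm(q, o)) for o in OFFSETS_13], "glcm"))
    out.update(
        _aggregate_directional(
            [glrlm_features(glrlm(q, o), n_vox) for o in OFFSETS_13], "glrlm"
        )
    )
    out.update({f"glszm_{k}": v for k, v in glszm_features(glszm(q), n_vox).items()})
    n, s = ngtdm(q)
    out.update({f"ngtdm_{k}": v for k, v in ngtdm_features(n, s).items()})
    out.update(lbp_features(volume, mask, config.lbp_radii, config.lbp_points))
    out.update(
        gabor_features(volume, mask, config.gabor_frequencies, config.gabor_angles_deg)
    )
    return out


def extract_voi_features(
    volume: np.ndarray, mask: np.ndarray, config: FeatureConfig
) -> tuple[dict[str, float], dict[str, str]]:
    """Orientation + histogram + texture features of one VOI, with family tags."""
    feats: dict[str, float] = {}
    fams: dict[str, str] = {}
    for k, v in orientation_features(mask).items():
        feats[f"orientation_{k}"] = v
        fams[f"orientation_{k}"] = "orientation"
    for k, v in histogram_features(volume, mask, config.histogram_bins).items():
        feats[f"histogram_{k}"] = v
        fams[f"histogram_{k}"] = "histogram"
    for k, v in texture_features(volume, mask, config).items():
        feats[k] = v
        fams[k] = "texture"
    return feats, fams


@dataclass
class FeatureTable:
    """A one-knee feature vector with per-column family tags."""

    values: pd.Series
    families: dict[str, str]

    def count(self, family: str, voi: str | None = None) -> int:
        cols = [
            c
            for c, f in self.families.items()
            if f == family and (voi is None or c.startswith(f"{voi}_") or family == "shape")
        ]
        return len(cols)


def extract_all(
    volume: ImageVolume,
    mask: np.ndarray,
    vois: VOISet,
    config: FeatureConfig | None = None,
) -> FeatureTable:
    """Extract the full per-knee feature vector.

    Per VOI: 3 orientation + 12 histogram + 271 texture features; for the
    whole tibia: 17 shape features. Column names are ``{VOI}_{feature}`` and
    ``shape_{feature}``; ordering is fixed; any non-finite value raises an
    error naming the feature and VOI.
    """
    config = config or FeatureConfig()
    config.validate_counts()
    values: dict[str, float] = {}
    families: dict[str, str] = {}
    for name in VOI_NAMES:
        box = vois[name]
        sub_v = volume.data[box.slices()]
        sub_m = mask[box.slices()]
        if not sub_m.any():
            raise ValueError(f"VOI {name} contains no mask voxels")
        feats, fams = extract_voi_features(sub_v, sub_m, config)
        for k, v in feats.items():
            col = f"{name}_{k}"
            if not np.isfinite(v):
                raise ValueError(f"non-finite feature {k!r} in VOI {name}")
            values[col] = v
            families[col] = fams[k]
    for k, v in shape_features(mask, volume.spacing).items():
        col = f"shape_{k}"
        if not np.isfinite(v):
            raise ValueError(f"non-finite shape feature {k!r}")
        values[col] = v
        families[col] = "shape"
    return FeatureTable(pd.Series(values), families)
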