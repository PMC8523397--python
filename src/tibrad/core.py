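"""Core containers and NIfTI I/O.

Axis convention used throughout the package: arrays are indexed ``(x, y, z)``
with ``x`` the medial-lateral (sagittal-slice) axis, ``y`` anterior-posterior,
and ``z`` the vertical (inferior -> superior) axis. Spacing is given in
millimetres per axis in the same order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

Spacing = tuple[float, float, float]


@dataclass
class ImageVolume:
    """A 3-D scalar grid with per-axis voxel spacing in mm."""

    data: np.ndarray
    spacing: Spacing

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "ImageVolume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=np.float64), spacing)  # type: ignore[arg-type]


def save_mask(mask: np.ndarray, spacing: Spacing, path: str | Path) -> None:
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def load_mask(path: str | Path) -> tuple[np.ndarray, Spacing]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj) > 0, spacing  # type: ignore[return-value]
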