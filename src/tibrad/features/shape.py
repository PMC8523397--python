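"""Whole-bone shape descriptors and mask orientation angles.

Shape is described by six slice-wise 2-D descriptors of the sagittal
cross-sections, each aggregated as mean and SD across slices, plus five
volumetric descriptors (17 values in total). Compactness follows the
classical definition 4*pi*area / perimeter^2, which is 1 for a circle and
drops as the outline becomes irregular; lower compactness of the tibial
cross-section is the shape signature associated with osteoarthritis.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.measure import (
    marching_cubes,
    mesh_surface_area,
    perimeter_crofton,
)
from skimage.morphology import convex_hull_image

from ..core import Spacing

SHAPE_SLICE_DESCRIPTORS = (
    "compactness",
    "convexity",
    "circular_variance",
    "radial_mean",
    "radial_sd",
    "eccentricity",
)
SHAPE_FEATURE_NAMES = tuple(
    f"{d}_{s}" for d in SHAPE_SLICE_DESCRIPTORS for s in ("mean", "sd")
) + ("volume", "surface_area", "sphericity", "extent", "elongation")

ORIENTATION_FEATURE_NAMES = ("azimuth_major", "polar_major", "azimuth_second")


def _slice_descriptors(sl: np.ndarray, pixel_mm: float) -> dict[str, float] | None:
    """2-D descriptors of one sagittal cross-section; None for < 2 pixels."""
    n = int(sl.sum())
    if n < 2:
        return None
    area = n * pixel_mm**2
    perim = perimeter_crofton(sl, directions=4) * pixel_mm
    if perim <= 0:
        return None
    compactness = 4.0 * np.pi * area / perim**2
    hull = convex_hull_image(sl)
    convexity = n / int(hull.sum())
    ys, zs = np.nonzero(sl)
    cy, cz = ys.mean(), zs.mean()
    boundary = sl & ~ndimage.binary_erosion(sl)
    by, bz = np.nonzero(boundary)
    d = np.hypot(by - cy, bz - cz) * pixel_mm
    dm = float(d.mean())
    dv = float(d.var())
    cov = np.cov(np.stack([ys, zs]) * pixel_mm) if n > 2 else np.eye(2)
    ev = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
    ecc = float(np.sqrt(1.0 - ev[1] / ev[0])) if ev[0] > 0 else 0.0
    return {
        "compactness": float(compactness),
        "convexity": float(convexity),
        "circular_variance": float(dv / dm**2) if dm > 0 else 0.0,
        "radial_mean": dm,
        "radial_sd": float(np.sqrt(dv)),
        "eccentricity": ecc,
    }


def shape_features(mask: np.ndarray, spacing_mm: Spacing) -> dict[str, float]:
    """17 shape descriptors of the whole tibial mask.

    Slice-wise descriptors assume (near-)isotropic in-plane spacing and use
    the mean of the y/z spacings as the pixel size. Single-voxel slices are
    skipped.
    """
    if not mask.any():
        raise ValueError("empty mask")
    pixel_mm = float((spacing_mm[1] + spacing_mm[2]) / 2.0)
    per_slice: list[dict[str, float]] = []
    for x in range(mask.shape[0]):
        d = _slice_descriptors(mask[x], pixel_mm)
        if d is not None:
            per_slice.append(d)
    if not per_slice:
        raise ValueError("no usable sagittal slices")
    out: dict[str, float] = {}
    for name in SHAPE_SLICE_DESCRIPTORS:
        vals = np.array([d[name] for d in per_slice])
        out[f"{name}_mean"] = float(vals.mean())
        out[f"{name}_sd"] = float(vals.std())

    voxvol = float(np.prod(spacing_mm))
    n = int(mask.sum())
    volume = n * voxvol
    padded = np.pad(mask, 1).astype(np.float64)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=spacing_mm)
    area = float(mesh_surface_area(verts, faces))
    out["volume"] = volume
    out["surface_area"] = area
    out["sphericity"] = float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area)
    bb = ndimage.find_objects(mask.astype(np.uint8))[0]
    bbox_n = int(np.prod([s.stop - s.start for s in bb]))
    out["extent"] = n / bbox_n
    coords = np.argwhere(mask) * np.asarray(spacing_mm)
    cov = np.cov(coords.T)
    ev = np.sort(np.linalg.eigvalsh(cov))[::-1]
    out["elongation"] = float(np.sqrt(ev[1] / ev[0])) if ev[0] > 0 else 1.0
    return out


def orientation_features(mask: np.ndarray, spacing_mm: Spacing = (1.0, 1.0, 1.0)) -> dict[str, float]:
    """Three principal-axis angles (degrees) from the second-moment tensor.

    ``azimuth_major``/``azimuth_second``: in-plane (x-y) direction of the
    first/second principal axis, in [0, 180); ``polar_major``: angle between
    the first principal axis and the vertical, in [0, 90].
    """
    if not mask.any():
        raise ValueError("empty mask")
    coords = np.argwhere(mask) * np.asarray(spacing_mm)
    cov = np.cov(coords.T)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    v = v[:, order]

    def azimuth(vec: np.ndarray) -> float:
        a = np.degrees(np.arctan2(vec[1], vec[0])) % 180.0
        return float(a)

    major, second = v[:, 0], v[:, 1]
    polar = float(np.degrees(np.arccos(np.clip(abs(major[2]), 0.0, 1.0))))
    return {
        "azimuth_major": azimuth(major),
        "polar_major": polar,
        "azimuth_second": azimuth(second),
    }
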