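"""Volume-of-interest placement on a segmented tibia.

Six axis-aligned boxes are placed per knee: subchondral (SBM/SBL), mid-part
(MidM/MidL), and trabecular (TBM/TBL) VOIs for the medial and lateral
compartments. The tibial spines are located as the two highest, horizontally
separated surface points; a vertical plane through the inter-spine midpoint
splits the compartments; in each compartment the subchondral VOI starts at
the cartilage-bone interface (proxied by the topmost bone voxel per column)
at the compartment's middle column and extends 10 mm down, with the mid and
trabecular VOIs stacked in the next two 10-mm tiers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import Spacing

VOI_NAMES: tuple[str, ...] = ("SBM", "MidM", "TBM", "SBL", "MidL", "TBL")


class SpineDetectionError(ValueError):
    pass


class CompartmentError(ValueError):
    pass


class InsufficientDepthError(ValueError):
    pass


@dataclass(frozen=True)
class Box:
    """Inclusive voxel index ranges per axis."""

    x: tuple[int, int]
    y: tuple[int, int]
    z: tuple[int, int]

    def __post_init__(self) -> None:
        for lo, hi in (self.x, self.y, self.z):
            if lo > hi:
                raise ValueError(f"empty box range {lo}..{hi}")

    def slices(self) -> tuple[slice, slice, slice]:
        return (
            slice(self.x[0], self.x[1] + 1),
            slice(self.y[0], self.y[1] + 1),
            slice(self.z[0], self.z[1] + 1),
        )

    def intersects(self, other: "Box") -> bool:
        for (a0, a1), (b0, b1) in zip(
            (self.x, self.y, self.z), (other.x, other.y, other.z)
        ):
            if a1 < b0 or b1 < a0:
                return False
        return True


@dataclass
class VOISet:
    boxes: dict[str, Box]
    spacing_mm: Spacing

    def __getitem__(self, name: str) -> Box:
        return self.boxes[name]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spacing_mm": list(self.spacing_mm),
            "boxes": {
                k: {"x": list(b.x), "y": list(b.y), "z": list(b.z)}
                for k, b in self.boxes.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "VOISet":
        payload = json.loads(Path(path).read_text())
        boxes = {
            k: Box(tuple(v["x"]), tuple(v["y"]), tuple(v["z"]))
            for k, v in payload["boxes"].items()
        }
        return cls(boxes, tuple(payload["spacing_mm"]))

    def label_map(self, shape: tuple[int, int, int]) -> np.ndarray:
        """NIfTI-style label volume with values 1-6 for visualization."""
        out = np.zeros(shape, dtype=np.uint8)
        for i, name in enumerate(VOI_NAMES, start=1):
            out[self.boxes[name].slices()] = i
        return out


def round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else int(np.ceil(x - 0.5))


def _height_map(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Topmost in-mask z index per (x, y) column; -1 where the column is empty."""
    occ = mask.any(axis=2)
    nz = mask.shape[2]
    top = nz - 1 - np.argmax(mask[:, :, ::-1], axis=2)
    return np.where(occ, top, -1), occ


def detect_tibial_spines(
    mask: np.ndarray, min_separation: int = 8
) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
    """Locate the two tibial spines on the segmented surface.

    Returns the highest surface voxel and the second-highest one at an
    in-plane distance of at least ``min_separation`` voxels, each as
    ``(x, y, z)``. Candidates are regional maxima of the column-height map;
    ties are broken toward the smaller medial-lateral (x) index. A flat-top
    mask (a single maximal region) raises ``SpineDetectionError``.
    """
    if not mask.any():
        raise SpineDetectionError("empty mask")
    h, occ = _height_map(mask)
    hf = np.where(occ, h, np.iinfo(np.int64).min)
    neigh_max = ndimage.maximum_filter(hf, size=3, mode="constant", cval=np.iinfo(np.int64).min)
    regmax = (hf >= neigh_max) & occ
    labels, n = ndimage.label(regmax, structure=np.ones((3, 3), dtype=bool))
    peaks = []  # (height, x, y) representative per maximal region
    for lab in range(1, n + 1):
        xs, ys = np.nonzero(labels == lab)
        heights = h[xs, ys]
        hmax = heights.max()
        cand = np.flatnonzero(heights == hmax)
        # representative = centroid of the peak cells (center of a flat top)
        cx = round_half_away(float(xs[cand].mean()))
        cy = round_half_away(float(ys[cand].mean()))
        peaks.append((int(hmax), cx, cy))
    peaks.sort(key=lambda p: (-p[0], p[1], p[2]))
    if len(peaks) < 2:
        raise SpineDetectionError("mask has no two separated height maxima")
    h1, x1, y1 = peaks[0]
    for h2, x2, y2 in peaks[1:]:
        if np.hypot(x2 - x1, y2 - y1) >= min_separation:
            return (x1, y1, h1), (x2, y2, h2)
    raise SpineDetectionError(
        f"no second height maximum at >= {min_separation} voxels separation"
    )


def split_compartments(
    mask: np.ndarray,
    spines: tuple[tuple[int, int, int], tuple[int, int, int]],
    laterality: str = "right",
) -> tuple[np.ndarray, np.ndarray]:
    """Partition tibia columns into medial and lateral compartment columns.

    Each compartment spans from its spine column to the outer border of the
    tibia; columns strictly between the spines form the inter-spine gap.
    Convention: for a right knee the medial compartment lies on the lower-x
    side; ``laterality='left'`` flips the assignment. Returns two boolean
    (nx, ny) column masks ``(medial, lateral)``.
    """
    if laterality not in ("right", "left"):
        raise ValueError("laterality must be 'right' or 'left'")
    (xa, _, _), (xb, _, _) = spines
    lo, hi = sorted((xa, xb))
    if hi - lo < 4:
        raise CompartmentError(f"spines too close: |dx| = {hi - lo} < 4 voxels")
    occ = mask.any(axis=2)
    xs = np.arange(mask.shape[0])[:, None]
    low_side = occ & (xs <= lo)
    high_side = occ & (xs >= hi)
    if laterality == "right":
        return low_side, high_side
    return high_side, low_side


def find_interface_depth(
    mask: np.ndarray, compartment: np.ndarray
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Per-column interface height and the compartment's middle-column anchor.

    The cartilage-bone interface is proxied by the topmost bone voxel of each
    column. The anchor is the interface height at the middle column of the
    compartment (midpoint of the occupied x range, then midpoint of the
    occupied y range at that x, snapped to occupied columns).
    """
    h, occ = _height_map(mask)
    region = compartment & occ
    if not region.any():
        raise CompartmentError("compartment contains no occupied columns")
    depth = np.where(region, h, -1)
    xs = np.nonzero(region.any(axis=1))[0]
    x_mid = round_half_away((xs.min() + xs.max()) / 2.0)
    x_mid = xs[np.argmin(np.abs(xs - x_mid))]
    ys = np.nonzero(region[x_mid])[0]
    y_mid = round_half_away((ys.min() + ys.max()) / 2.0)
    y_mid = ys[np.argmin(np.abs(ys - y_mid))]
    return depth, (int(x_mid), int(y_mid), int(h[x_mid, y_mid]))


def _central_range(lo: int, hi: int, fraction: float) -> tuple[int, int]:
    span = hi - lo + 1
    width = max(1, round_half_away(fraction * span))
    start = lo + (span - width) // 2
    return start, start + width - 1


def extract_vois(
    mask: np.ndarray,
    spacing_mm: Spacing,
    voi_height_mm: float = 10.0,
    central_fraction: float = 0.8,
    laterality: str = "right",
    min_separation: int = 8,
) -> VOISet:
    """Place the six VOIs on a segmented tibia mask.

    Per compartment: the subchondral box runs from the interface anchor down
    ``voi_height_mm``; the mid and trabecular boxes occupy the next two tiers
    of the same height. The horizontal extent is the central
    ``central_fraction`` of the compartment's occupied span, clipped to the
    mask bounding box. Raises ``InsufficientDepthError`` naming the
    compartment when the bone below the anchor is shallower than three tiers.
    """
    spines = detect_tibial_spines(mask, min_separation=min_separation)
    medial, lateral = split_compartments(mask, spines, laterality=laterality)
    h_vox = round_half_away(voi_height_mm / spacing_mm[2])
    if h_vox < 1:
        raise ValueError("VOI height below one voxel")

    bb = ndimage.find_objects(mask.astype(np.uint8))[0]
    bx = (bb[0].start, bb[0].stop - 1)
    by = (bb[1].start, bb[1].stop - 1)
    bz = (bb[2].start, bb[2].stop - 1)

    boxes: dict[str, Box] = {}
    for comp_name, region, names in (
        ("medial", medial, ("SBM", "MidM", "TBM")),
        ("lateral", lateral, ("SBL", "MidL", "TBL")),
    ):
        _, (ax, ay, az) = find_interface_depth(mask, region)
        zs_col = np.nonzero(mask[ax, ay])[0]
        depth_vox = az - zs_col.min() + 1
        if depth_vox < 3 * h_vox:
            raise InsufficientDepthError(
                f"{comp_name} compartment: bone depth {depth_vox * spacing_mm[2]:.1f} mm "
                f"< {3 * h_vox * spacing_mm[2]:.1f} mm required for three tiers"
            )
        xs = np.nonzero(region.any(axis=1))[0]
        ys = np.nonzero(region.any(axis=0))[0]
        x0, x1 = _central_range(xs.min(), xs.max(), central_fraction)
        y0, y1 = _central_range(ys.min(), ys.max(), central_fraction)
        x0, x1 = max(x0, bx[0]), min(x1, bx[1])
        y0, y1 = max(y0, by[0]), min(y1, by[1])
        for tier, name in enumerate(names):
            z_hi = az - tier * h_vox
            z_lo = z_hi - h_vox + 1
            z_lo, z_hi = max(z_lo, bz[0]), min(z_hi, bz[1])
            boxes[name] = Box((int(x0), int(x1)), (int(y0), int(y1)), (int(z_lo), int(z_hi)))

    names = list(boxes)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if boxes[a].intersects(boxes[b]):
                raise CompartmentError(f"VOIs {a} and {b} intersect")
    return VOISet(boxes, spacing_mm)
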