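"""Synthetic knee-phantom cohort generator.

Real FIESTA knee MRI of the study population is not publicly deposited, so
every downstream stage is exercised on synthetic tibia-like phantoms that
carry the statistical structure the analysis assumes:

* a shaft flaring into a plateau that bears two spines (intercondylar
  tubercles) of distinct heights, so spine detection and compartment
  splitting have a ground truth;
* class-dependent intratrabecular texture: a stationary correlated Gaussian
  field whose correlation length is longer for OA knees, making OA texture
  more homogeneous (lower local intensity variance at equal marginal SD);
* class-dependent plateau irregularity: a sinusoidal radial perturbation of
  the outline whose lobes twist with height, lowering slice-wise compactness
  for OA knees;
* covariates (age, BMI) drawn from the cohort's normal distributions and, by
  default, independent of the labels;
* MOAKS records sampled by inverting the label rules, so that re-classifying
  a generated record reproduces the requested labels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import ImageVolume, Spacing
from .moaks import (
    KneeLabels,
    MoaksRecord,
    label_knee,
)


class PhantomSizingError(ValueError):
    """The requested grid cannot hold the plateau plus 30 mm of bone depth."""


@dataclass(frozen=True)
class ClassEffect:
    """Texture/shape parameters for one class (control or OA)."""

    texture_corr_len_mm: float = 0.5
    texture_sd: float = 20.0
    surface_irregularity_amp: float = 0.0


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, texture, and noise parameters of the tibia phantom.

    The grid must be tall enough to hold the plateau, the spines, and 30 mm
    of bone depth below the cartilage-bone interface (three stacked 10-mm VOI
    tiers). The OA texture correlation length must exceed the control one:
    that inequality is what encodes "more homogeneous OA texture".
    """

    grid_shape: tuple[int, int, int] = (80, 80, 96)
    spacing_mm: Spacing = (0.5, 0.5, 0.5)
    shaft_radius_mm: float = 13.5
    plateau_width_mm: float = 30.0
    spine_height_mm: tuple[float, float] = (6.0, 4.0)
    spine_separation_mm: float = 12.0
    spine_sigma_mm: float = 3.0
    flare_length_mm: float = 10.0
    irregularity_lobes: int = 6
    irregularity_twist_period_mm: float = 8.0
    base_intensity: float = 100.0
    noise_sd: float = 2.0
    geometry_jitter: float = 0.08
    control: ClassEffect = field(default_factory=lambda: ClassEffect())
    oa: ClassEffect = field(
        default_factory=lambda: ClassEffect(
            texture_corr_len_mm=2.0, surface_irregularity_amp=0.25
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = (
            self.shaft_radius_mm,
            self.plateau_width_mm,
            *self.spine_height_mm,
            self.spine_separation_mm,
            self.spine_sigma_mm,
            self.flare_length_mm,
            *self.spacing_mm,
        )
        if any(v <= 0 for v in lengths):
            raise ValueError("all lengths must be positive")
        if self.oa.texture_corr_len_mm <= self.control.texture_corr_len_mm:
            raise ValueError(
                "OA texture correlation length must exceed the control one "
                "(OA texture is the more homogeneous class)"
            )
        # plateau top sits below the grid top by the tallest spine + margin;
        # worst-case jitter must still leave three 10-mm tiers of depth
        worst_drop = self.geometry_jitter * (4.0 + max(self.spine_height_mm))
        if self.plateau_top_mm() - worst_drop < 31.0:
            raise PhantomSizingError(
                "grid too small: need >= 31 mm of bone below the plateau for "
                "three stacked 10-mm VOI tiers"
            )
        if self.plateau_width_mm >= min(
            self.grid_shape[0] * self.spacing_mm[0],
            self.grid_shape[1] * self.spacing_mm[1],
        ):
            raise PhantomSizingError("grid too small to hold the plateau width")

    def plateau_top_mm(self) -> float:
        """Height (mm above the grid bottom) of the flat plateau surface."""
        return self.grid_shape[2] * self.spacing_mm[2] - max(self.spine_height_mm) - 1.5

    def effect(self, oa_class: bool) -> ClassEffect:
        return self.oa if oa_class else self.control


def _grid_coords(params: PhantomParams):
    nx, ny, nz = params.grid_shape
    sx, sy, sz = params.spacing_mm
    x = (np.arange(nx) - (nx - 1) / 2.0) * sx
    y = (np.arange(ny) - (ny - 1) / 2.0) * sy
    z = np.arange(nz) * sz
    return x[:, None, None], y[None, :, None], z[None, None, :]


@dataclass(frozen=True)
class _Geometry:
    """Per-phantom realized geometry (mm), jittered around the parameter means."""

    shaft_radius: float
    plateau_radius: float
    spine_heights: tuple[float, float]
    spine_separation: float
    center: tuple[float, float]
    z_plateau: float


def _sample_geometry(params: PhantomParams, rng: np.random.Generator) -> _Geometry:
    """Draw the subject-specific geometry; jitter = 0 gives the exact means.

    Anatomical variability across subjects is what makes atlas registration a
    real problem on phantoms; the jitter fraction scales relative deviations
    of radii/heights and a small in-plane center offset.
    """
    j = params.geometry_jitter
    u = lambda: 1.0 + j * rng.uniform(-1.0, 1.0)  # noqa: E731
    shaft = params.shaft_radius_mm * u()
    plateau = max(params.plateau_width_mm / 2.0 * u(), shaft + 0.5)
    h1, h2 = params.spine_height_mm
    heights = (h1 * u(), h2 * u())
    sep = params.spine_separation_mm * u()
    center = (
        2.0 * j * params.shaft_radius_mm * rng.uniform(-1.0, 1.0),
        2.0 * j * params.shaft_radius_mm * rng.uniform(-1.0, 1.0),
    )
    z_plateau = (
        params.grid_shape[2] * params.spacing_mm[2]
        - max(heights)
        - 1.5
        - j * 4.0 * rng.uniform(0.0, 1.0)
    )
    return _Geometry(shaft, plateau, heights, sep, center, z_plateau)


def _spine_centers_mm(geom: _Geometry) -> tuple[tuple[float, float], tuple[float, float]]:
    half = geom.spine_separation / 2.0
    cx, cy = geom.center
    return (cx - half, cy), (cx + half, cy)  # (x, y); taller spine at lower x


def generate_tibia_phantom(
    params: PhantomParams, oa_class: bool
) -> tuple[ImageVolume, np.ndarray]:
    """Generate one phantom volume and its ground-truth tibia mask.

    The mask is a single 6-connected component whose plateau bears exactly
    two local-maximum spines of distinct heights. The volume is a constant
    base intensity plus a correlated Gaussian field inside the mask plus
    i.i.d. noise everywhere; everything is deterministic given ``params.seed``.
    """
    eff = params.effect(oa_class)
    x, y, z = _grid_coords(params)
    sx, sy, sz = params.spacing_mm

    rng = np.random.default_rng(params.seed)
    geom = _sample_geometry(params, rng)
    z_plateau = geom.z_plateau
    if z_plateau < 31.0:
        raise PhantomSizingError(
            "grid too small after geometry sampling: plateau sits below 31 mm"
        )
    # smooth flare from shaft radius to plateau radius over flare_length_mm
    s = np.clip((z - (z_plateau - params.flare_length_mm)) / params.flare_length_mm, 0.0, 1.0)
    s = s * s * (3.0 - 2.0 * s)  # smoothstep
    radius = geom.shaft_radius + (geom.plateau_radius - geom.shaft_radius) * s

    theta = np.arctan2(y - geom.center[1], x - geom.center[0])
    if eff.surface_irregularity_amp > 0:
        # Inward-only scalloping (range [1-amp, 1] of the radius): lowers
        # slice compactness without inflating the footprint; the lobes twist
        # with height so sagittal silhouettes are wavy too.
        phase = 2.0 * np.pi * z / params.irregularity_twist_period_mm
        radius = radius * (
            1.0
            + eff.surface_irregularity_amp
            * (np.sin(params.irregularity_lobes * theta + phase) - 1.0)
            / 2.0
            * s
        )

    (x1, y1), (x2, y2) = _spine_centers_mm(geom)
    h1, h2 = geom.spine_heights
    sig2 = 2.0 * params.spine_sigma_mm**2
    z_top = (
        z_plateau
        + h1 * np.exp(-((x - x1) ** 2 + (y - y1) ** 2) / sig2)
        + h2 * np.exp(-((x - x2) ** 2 + (y - y2) ** 2) / sig2)
    )

    rho = np.sqrt((x - geom.center[0]) ** 2 + (y - geom.center[1]) ** 2)
    mask = (rho <= radius) & (z <= z_top)
    if not mask.any():
        raise PhantomSizingError("empty phantom mask")

    white = rng.standard_normal(params.grid_shape)
    noise = (
        rng.normal(0.0, params.noise_sd, params.grid_shape)
        if params.noise_sd > 0
        else 0.0
    )

    volume = np.zeros(params.grid_shape, dtype=np.float64)
    if eff.texture_sd > 0:
        sigma_vox = [eff.texture_corr_len_mm / sp for sp in (sx, sy, sz)]
        fld = gaussian_filter(white, sigma=sigma_vox)
        sd = fld[mask].std()
        if sd > 0:
            fld = fld * (eff.texture_sd / sd)
        volume[mask] = fld[mask]
    volume[mask] += params.base_intensity
    volume = volume + noise

    return ImageVolume(volume, params.spacing_mm), mask


def phantom_landmarks(params: PhantomParams) -> dict[str, tuple[int, int]]:
    """Ground-truth voxel columns (x, y) of the two spines (taller first).

    Re-derives the seeded per-phantom geometry, so the returned columns match
    what ``generate_tibia_phantom`` actually built for the same params.
    """
    rng = np.random.default_rng(params.seed)
    geom = _sample_geometry(params, rng)
    nx, ny, _ = params.grid_shape
    sx, sy, _ = params.spacing_mm
    out = {}
    for name, (cx, cy) in zip(("spine_tall", "spine_short"), _spine_centers_mm(geom)):
        ix = int(round(cx / sx + (nx - 1) / 2.0))
        iy = int(round(cy / sy + (ny - 1) / 2.0))
        out[name] = (ix, iy)
    return out


# ---------------------------------------------------------------------------
# cohort table


def _stratified_labels(n: int, prevalence: float, rng: np.random.Generator) -> np.ndarray:
    n_pos = int(round(n * prevalence))
    if n_pos < 1:
        raise ValueError(f"n*prevalence = {n * prevalence:.3f} < 1: no positive knees")
    labels = np.zeros(n, dtype=bool)
    labels[:n_pos] = True
    rng.shuffle(labels)
    return labels


def generate_cohort(
    n: int,
    prevalence: float,
    params: PhantomParams,
    seed: int,
    sub_prevalence: tuple[float, float, float] = (0.137, 0.128, 0.105),
    age_mean: float = 54.6,
    age_sd: float = 3.7,
    bmi_mean: float = 26.8,
    bmi_sd: float = 4.6,
    covariate_association: float = 0.0,
) -> pd.DataFrame:
    """Generate the cohort table: one row per knee.

    Exactly ``round(n * prevalence)`` knees receive a positive tfOA label
    (stratified, not Bernoulli, for test stability); the three medial
    sub-outcome labels are stratified analogously at their own prevalences.
    Age and BMI are normal draws, by default independent of the labels;
    ``covariate_association`` shifts the mean age/BMI of positive knees by
    that many SDs when non-zero.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must be in (0, 1)")
    if n < 10:
        raise ValueError("n must be >= 10")
    rng = np.random.default_rng(seed)
    tfoa = _stratified_labels(n, prevalence, rng)
    cart = _stratified_labels(n, sub_prevalence[0], rng)
    osteo = _stratified_labels(n, sub_prevalence[1], rng)
    bml = _stratified_labels(n, sub_prevalence[2], rng)
    age = rng.normal(age_mean, age_sd, n)
    bmi = rng.normal(bmi_mean, bmi_sd, n)
    if covariate_association:
        age = age + covariate_association * age_sd * tfoa
        bmi = bmi + covariate_association * bmi_sd * tfoa
    age = np.abs(age)
    bmi = np.abs(bmi)
    phantom_seed = rng.integers(0, 2**31 - 1, size=n)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "age": age,
            "bmi": bmi,
            "label_tfoa": tfoa,
            "label_cartilage": cart,
            "label_osteophyte": osteo,
            "label_bml": bml,
            "phantom_seed": phantom_seed,
        }
    )


def phantom_for_row(row, params: PhantomParams) -> tuple[ImageVolume, np.ndarray]:
    """Generate the phantom for one cohort row (seed and class from the row)."""
    p = replace(params, seed=int(row["phantom_seed"]))
    return generate_tibia_phantom(p, bool(row["label_tfoa"]))


# ---------------------------------------------------------------------------
# MOAKS record sampling (inverse of the label rules)


def generate_moaks_record(labels: KneeLabels, seed: int) -> MoaksRecord:
    """Sample a MOAKS record that classifies back to ``labels`` exactly.

    Construction: medial sub-outcome flags place grade-1..2 findings at
    medial tibial sites; the tfOA flag is realized either by both primary
    features or by one primary plus two secondaries, placing primaries at
    non-medial sites whenever the corresponding medial flag is off.
    """
    rng = np.random.default_rng(seed)
    rec = MoaksRecord()

    if labels.medial_cartilage_damage:
        site = CART_MEDIAL[rng.integers(len(CART_MEDIAL))]
        rec.cartilage[site] = int(rng.integers(1, 3))  # grade 1 or 2, never full
    if labels.medial_osteophyte:
        rec.osteophyte["medial_tibia"] = 1  # present but not definite
    if labels.medial_bml:
        site = CART_MEDIAL[rng.integers(len(CART_MEDIAL))]
        rec.bml[site] = int(rng.integers(1, 4))

    if labels.tfoa:
        # Sites for primaries that do not disturb the medial sub-labels.
        osteo_site = "medial_tibia" if labels.medial_osteophyte else "lateral_femur"
        cart_site = "lateral_femur"
        mode = rng.integers(3)
        if mode == 0:  # both primaries
            rec.osteophyte[osteo_site] = int(rng.integers(2, 4))
            rec.cartilage[cart_site] = 3
        elif mode == 1:  # definite osteophyte + two secondaries
            rec.osteophyte[osteo_site] = int(rng.integers(2, 4))
            rec.meniscus_degeneration_grade = 1
            if labels.medial_bml:
                rec.bml_or_cyst_nonattachment = True
            else:
                rec.bml["lateral_femur"] = 1
                rec.bml_or_cyst_nonattachment = True
        else:  # full-thickness cartilage loss + two secondaries
            rec.cartilage[cart_site] = 3
            rec.meniscus_degeneration_grade = 1
            if rng.integers(2):
                rec.meniscus_horizontal_tear = True
            if labels.medial_bml:
                rec.bml_or_cyst_nonattachment = True
            else:
                rec.bml["lateral_femur"] = 1
                rec.bml_or_cyst_nonattachment = True
    else:
        # No primary feature may appear: medial findings above are grade <= 2
        # osteophytes grade <= 1 and cartilage grades <= 2 already guarantee it.
        # BML presence without a primary never classifies positive.
        if labels.medial_bml and rng.integers(2):
            rec.bml_or_cyst_nonattachment = True

    got = label_knee(rec)
    if got != labels:  # defensive: construction is exact by design
        raise AssertionError(f"round-trip mismatch: wanted {labels}, got {got}")
    return rec


CART_MEDIAL = (
    "medial_tibia_anterior",
    "medial_tibia_central",
    "medial_tibia_posterior",
)


def generate_moaks_records(cohort: pd.DataFrame, seed: int) -> list[MoaksRecord]:
    """One record per cohort row, seeded per subject."""
    records = []
    for i, row in cohort.iterrows():
        lab = KneeLabels(
            tfoa=bool(row["label_tfoa"]),
            medial_cartilage_damage=bool(row["label_cartilage"]),
            medial_osteophyte=bool(row["label_osteophyte"]),
            medial_bml=bool(row["label_bml"]),
        )
        records.append(generate_moaks_record(lab, seed=int(seed) * 1000003 % (2**31) + i))
    return records
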