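"""Tibia segmentation: multi-atlas registration fused with an appearance model.

The multi-atlas component registers each atlas image to the target (affine
stage followed by a B-spline free-form stage, Mattes mutual information for
both), warps the atlas masks with nearest-neighbour interpolation, and
averages them into a per-voxel tibia probability. The appearance component
is a random forest voxel classifier over a 49-channel Gaussian scale-space
feature stack. The final mask thresholds a weighted mean of the two
probability maps and keeps the largest 6-connected component.

The registration backend (SimpleITK) is pluggable behind the
``register_atlas`` contract: any backend providing an affine-then-nonrigid
transform optimized under mutual information satisfies it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .core import ImageVolume, Spacing

DEFAULT_SCALES_MM = (0.5, 1.0, 2.0)

#: Channel layout: raw intensity + 16 channels per scale.
PER_SCALE_CHANNELS = (
    ["smoothed", "dx", "dy", "dz", "hxx", "hxy", "hxz", "hyy", "hyz", "hzz",
     "gradient_magnitude", "laplacian", "gaussian_curvature", "eig1", "eig2", "eig3"]
)


def scale_space_channel_names(scales_mm: tuple[float, ...] = DEFAULT_SCALES_MM) -> list[str]:
    names = ["intensity"]
    for s in scales_mm:
        names.extend(f"{c}@{s:g}mm" for c in PER_SCALE_CHANNELS)
    return names


def _gaussian_deriv_kernel(sigma: float, order: int, truncate: float = 4.0) -> np.ndarray:
    """Sampled Gaussian-derivative kernel, moment-corrected for small sigma.

    The raw sampled kernel is renormalized so that (a) derivative kernels are
    exactly zero-sum (a constant image has zero derivative everywhere) and
    (b) the response to the monomial x^order / order! is exactly 1, i.e. unit
    gain on the polynomial the derivative should pick out.
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    radius = max(1, int(truncate * sigma + 0.5))
    x = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g /= g.sum()
    if order == 0:
        return g
    if order == 1:
        k = -(x / sigma**2) * g  # odd: zero-sum by symmetry
        # correlate1d convention: response to f(x)=x is sum(k(x) * x); force +1
        gain = float((k * x).sum())
        return k / gain
    k = ((x**2 / sigma**4) - 1.0 / sigma**2) * g
    k -= k.mean()  # exact zero-sum
    gain = float((k * x**2 / 2.0).sum())
    return k / gain


def compute_scale_space_features(
    image: ImageVolume, scales_mm: tuple[float, ...] = DEFAULT_SCALES_MM
) -> np.ndarray:
    """49-channel Gaussian scale-space stack, shape (49, nx, ny, nz).

    Channels: raw intensity, then per scale the smoothed image, the three
    first Gaussian derivatives, the six Hessian entries, gradient magnitude,
    Laplacian, Gaussian curvature (Hessian determinant), and the three
    Hessian eigenvalues sorted descending. Derivatives are per-mm (spacing
    aware).
    """
    if len(scales_mm) != 3 or any(s <= 0 for s in scales_mm):
        raise ValueError("need 3 positive scales (mm)")
    data = np.asarray(image.data, dtype=np.float64)
    sp = np.asarray(image.spacing)
    chans: list[np.ndarray] = [data]
    for scale in scales_mm:
        sigma = scale / sp  # voxels per axis

        def deriv(orders: tuple[int, int, int]) -> np.ndarray:
            out = data
            for axis, (s, o) in enumerate(zip(sigma, orders)):
                out = ndimage.correlate1d(out, _gaussian_deriv_kernel(s, o), axis=axis, mode="reflect")
            return out / np.prod(sp**np.array(orders))

        g = deriv((0, 0, 0))

        dx, dy, dz = deriv((1, 0, 0)), deriv((0, 1, 0)), deriv((0, 0, 1))
        hxx, hyy, hzz = deriv((2, 0, 0)), deriv((0, 2, 0)), deriv((0, 0, 2))
        hxy, hxz, hyz = deriv((1, 1, 0)), deriv((1, 0, 1)), deriv((0, 1, 1))
        grad = np.sqrt(dx**2 + dy**2 + dz**2)
        lap = hxx + hyy + hzz
        # Hessian determinant (the Gaussian-curvature channel)
        det = (
            hxx * (hyy * hzz - hyz**2)
            - hxy * (hxy * hzz - hyz * hxz)
            + hxz * (hxy * hyz - hyy * hxz)
        )
        H = np.stack(
            [
                np.stack([hxx, hxy, hxz], axis=-1),
                np.stack([hxy, hyy, hyz], axis=-1),
                np.stack([hxz, hyz, hzz], axis=-1),
            ],
            axis=-2,
        )
        eig = np.linalg.eigvalsh(H)[..., ::-1]  # descending
        chans.extend(
            [g, dx, dy, dz, hxx, hxy, hxz, hyy, hyz, hzz, grad, lap, det,
             eig[..., 0], eig[..., 1], eig[..., 2]]
        )
    stack = np.stack(chans)
    if not np.isfinite(stack).all():
        bad = int(np.nonzero(~np.isfinite(stack).reshape(stack.shape[0], -1).all(axis=1))[0][0])
        raise ValueError(f"non-finite values in scale-space channel {bad}")
    return stack


# ---------------------------------------------------------------------------
# registration


@dataclass
class RegistrationConfig:
    mi_bins: int = 32
    affine_iterations: int = 150
    affine_shrink: tuple[int, ...] = (4, 2, 1)
    affine_smooth: tuple[float, ...] = (2.0, 1.0, 0.0)
    bspline_mesh: tuple[int, int, int] = (4, 4, 4)
    bspline_iterations: int = 25
    bspline_shrink: tuple[int, ...] = (2,)
    bspline_smooth: tuple[float, ...] = (1.0,)
    sampling_fraction: float = 0.1
    mi_tolerance: float = 0.05  # relative MI slack for the convergence flag
    seed: int = 12345


@dataclass
class RegistrationResult:
    """Transform mapping atlas space to target space, with MI diagnostics."""

    transform: sitk.Transform
    initial_mi: float
    final_mi: float
    converged: bool
    message: str = ""


def _to_sitk(vol: ImageVolume) -> sitk.Image:
    # numpy (x, y, z) -> sitk expects (z, y, x) arrays
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T).astype(np.float32))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    return img


def _mask_to_sitk(mask: np.ndarray, spacing: Spacing) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(mask.T).astype(np.uint8))
    img.SetSpacing(tuple(float(s) for s in spacing))
    return img


def _from_sitk(img: sitk.Image) -> np.ndarray:
    return sitk.GetArrayFromImage(img).T


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Joint-histogram mutual information estimate (nats)."""
    h, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = h / h.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


def _mi_method(config: RegistrationConfig) -> sitk.ImageRegistrationMethod:
    r = sitk.ImageRegistrationMethod()
    r.SetMetricAsMattesMutualInformation(numberOfHistogramBins=config.mi_bins)
    r.SetMetricSamplingStrategy(r.REGULAR)
    r.SetMetricSamplingPercentage(config.sampling_fraction, config.seed)
    r.SetInterpolator(sitk.sitkLinear)
    return r


def register_atlas(
    atlas_image: ImageVolume,
    target_image: ImageVolume,
    config: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Affine followed by B-spline registration under mutual information.

    Registration failure never passes silently: if the registered image's
    mutual information with the target is below the identity baseline, the
    result is flagged ``converged=False`` with a diagnostic message.
    """
    if atlas_image.data.ndim != target_image.data.ndim:
        raise ValueError("volumes must share dimensionality")
    config = config or RegistrationConfig()
    fixed = _to_sitk(target_image)
    moving = _to_sitk(atlas_image)

    initial_mi = mutual_information(target_image.data, atlas_image.data, config.mi_bins)

    affine0 = sitk.CenteredTransformInitializer(
        fixed, moving, sitk.AffineTransform(3), sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    reg = _mi_method(config)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-4,
        numberOfIterations=config.affine_iterations,
        relaxationFactor=0.5,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(config.affine_shrink))
    reg.SetSmoothingSigmasPerLevel(list(config.affine_smooth))
    reg.SetInitialTransform(affine0, inPlace=False)
    message = ""
    try:
        affine = reg.Execute(fixed, moving)
    except RuntimeError as exc:  # diagnostics, never silent
        return RegistrationResult(affine0, initial_mi, initial_mi, False, str(exc))

    bspline0 = sitk.BSplineTransformInitializer(fixed, list(config.bspline_mesh))
    reg2 = _mi_method(config)
    reg2.SetOptimizerAsLBFGSB(numberOfIterations=config.bspline_iterations)
    reg2.SetShrinkFactorsPerLevel(list(config.bspline_shrink))
    reg2.SetSmoothingSigmasPerLevel(list(config.bspline_smooth))
    reg2.SetInitialTransform(bspline0, inPlace=False)
    reg2.SetMovingInitialTransform(affine)
    try:
        bspline = reg2.Execute(fixed, moving)
        composite = sitk.CompositeTransform([affine, bspline])
    except RuntimeError as exc:
        composite = affine
        message = f"non-rigid stage failed, affine retained: {exc}"

    warped = sitk.Resample(moving, fixed, composite, sitk.sitkLinear, 0.0)
    final_mi = mutual_information(target_image.data, _from_sitk(warped), config.mi_bins)
    # Never return a transform worse than identity: if optimization lost MI
    # (e.g. self-registration, where any interpolation degrades a degenerate
    # perfect match), fall back to the identity transform.
    if final_mi < initial_mi * (1.0 - config.mi_tolerance):
        composite = sitk.Transform(3, sitk.sitkIdentity)
        final_mi = initial_mi
        message = message or "optimizer did not beat identity; identity returned"
        converged = True
    else:
        # small slack: interpolation smoothing alone lowers the histogram MI
        converged = final_mi >= initial_mi * (1.0 - config.mi_tolerance)
        if not converged and not message:
            message = f"final MI {final_mi:.4f} below identity baseline {initial_mi:.4f}"
    return RegistrationResult(composite, initial_mi, final_mi, converged, message)


def apply_transform_to_mask(
    mask: np.ndarray,
    spacing: Spacing,
    transform: sitk.Transform,
    target_grid: ImageVolume,
) -> np.ndarray:
    """Nearest-neighbour warp of a label mask onto the target grid."""
    m = _mask_to_sitk(mask, spacing)
    ref = _to_sitk(target_grid)
    warped = sitk.Resample(m, ref, transform, sitk.sitkNearestNeighbor, 0)
    return _from_sitk(warped) > 0


def propagate_and_average(
    atlas_masks: list[np.ndarray],
    transforms: list[sitk.Transform | None],
    target_grid: ImageVolume,
    atlas_spacing: Spacing | None = None,
) -> np.ndarray:
    """Per-voxel mean of the warped atlas masks (a probability map in [0, 1]).

    A ``None`` transform means identity; masks must then already live on the
    target grid.
    """
    if len(atlas_masks) != len(transforms):
        raise ValueError("one transform per atlas mask required")
    acc = np.zeros(target_grid.shape, dtype=np.float64)
    for mask, tf in zip(atlas_masks, transforms):
        if tf is None:
            if mask.shape != target_grid.shape:
                raise ValueError("grid mismatch for identity-transform mask")
            acc += mask
        else:
            sp = atlas_spacing or target_grid.spacing
            acc += apply_transform_to_mask(mask, sp, tf, target_grid)
    return acc / len(atlas_masks)


# ---------------------------------------------------------------------------
# appearance model


@dataclass
class VoxelClassifier:
    """Random forest over the 49-channel scale-space stack."""

    forest: RandomForestClassifier
    scales_mm: tuple[float, ...]

    def predict_probability(self, image: ImageVolume) -> np.ndarray:
        stack = compute_scale_space_features(image, self.scales_mm)
        X = stack.reshape(stack.shape[0], -1).T
        p = self.forest.predict_proba(X)[:, 1]
        return p.reshape(image.shape)


def train_appearance_classifier(
    atlases: list[tuple[ImageVolume, np.ndarray]],
    scales_mm: tuple[float, ...] = DEFAULT_SCALES_MM,
    voxels_per_class: int = 2000,
    n_trees: int = 100,
    seed: int = 0,
) -> VoxelClassifier:
    """Train the voxel classifier on balanced samples from the atlas set."""
    if not atlases:
        raise ValueError("need at least one atlas")
    rng = np.random.default_rng(seed)
    Xs, ys = [], []
    for vol, mask in atlases:
        stack = compute_scale_space_features(vol, scales_mm)
        flat = stack.reshape(stack.shape[0], -1).T
        lab = mask.ravel()
        pos = np.flatnonzero(lab)
        neg = np.flatnonzero(~lab)
        if pos.size == 0 or neg.size == 0:
            raise ValueError("atlas contains a single class of voxels")
        take_pos = rng.choice(pos, size=min(voxels_per_class, pos.size), replace=False)
        take_neg = rng.choice(neg, size=min(voxels_per_class, neg.size), replace=False)
        idx = np.concatenate([take_pos, take_neg])
        Xs.append(flat[idx])
        ys.append(lab[idx])
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=int(seed) % (2**31), n_jobs=1
    )
    forest.fit(X, y)
    return VoxelClassifier(forest, tuple(scales_mm))


# ---------------------------------------------------------------------------
# fusion and evaluation

_CONN6 = ndimage.generate_binary_structure(3, 1)


def fuse_and_threshold(
    p_atlas: np.ndarray,
    p_appearance: np.ndarray,
    weight: float = 0.5,
    threshold: float = 0.5,
) -> np.ndarray:
    """Weighted-mean fusion, thresholding, largest 6-connected component."""
    if p_atlas.shape != p_appearance.shape:
        raise ValueError("probability maps on different grids")
    if not (0.0 <= weight <= 1.0):
        raise ValueError("weight must be in [0, 1]")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    combined = weight * p_atlas + (1.0 - weight) * p_appearance
    binary = combined >= threshold
    if not binary.any():
        return binary
    lab, n = ndimage.label(binary, structure=_CONN6)
    if n > 1:
        sizes = np.bincount(lab.ravel())[1:]
        binary = lab == (int(np.argmax(sizes)) + 1)
    return binary


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|)."""
    if a.shape != b.shape:
        raise ValueError("masks on different grids")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("Dice undefined for two empty masks")
    return 2.0 * int((a & b).sum()) / (na + nb)


# ---------------------------------------------------------------------------
# convenience drivers


def multiatlas_probability(
    target: ImageVolume,
    atlases: list[tuple[ImageVolume, np.ndarray]],
    config: RegistrationConfig | None = None,
    nonrigid: bool = True,
) -> np.ndarray:
    """Register every atlas to the target and average the warped masks.

    ``nonrigid=False`` truncates each registration to its affine stage
    (baseline used to quantify the benefit of the non-rigid stage).
    """
    config = config or RegistrationConfig()
    if not nonrigid:
        config = RegistrationConfig(
            **{**config.__dict__, "bspline_iterations": 0}
        )
        config.bspline_iterations = 0
    masks, tfs = [], []
    for vol, mask in atlases:
        if config.bspline_iterations == 0:
            res = _register_affine_only(vol, target, config)
        else:
            res = register_atlas(vol, target, config)
        masks.append(mask)
        tfs.append(res.transform)
    return propagate_and_average(masks, tfs, target, atlases[0][0].spacing)


def _register_affine_only(
    atlas_image: ImageVolume, target_image: ImageVolume, config: RegistrationConfig
) -> RegistrationResult:
    fixed = _to_sitk(target_image)
    moving = _to_sitk(atlas_image)
    initial_mi = mutual_information(target_image.data, atlas_image.data, config.mi_bins)
    affine0 = sitk.CenteredTransformInitializer(
        fixed, moving, sitk.AffineTransform(3), sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    reg = _mi_method(config)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4,
        numberOfIterations=config.affine_iterations, relaxationFactor=0.5,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(config.affine_shrink))
    reg.SetSmoothingSigmasPerLevel(list(config.affine_smooth))
    reg.SetInitialTransform(affine0, inPlace=False)
    affine = reg.Execute(fixed, moving)
    warped = sitk.Resample(moving, fixed, affine, sitk.sitkLinear, 0.0)
    final_mi = mutual_information(target_image.data, _from_sitk(warped), config.mi_bins)
    return RegistrationResult(affine, initial_mi, final_mi, final_mi >= initial_mi)


def segment_tibia(
    target: ImageVolume,
    atlases: list[tuple[ImageVolume, np.ndarray]],
    classifier: VoxelClassifier | None = None,
    config: RegistrationConfig | None = None,
    weight: float = 0.5,
    threshold: float = 0.5,
    qc_dice_threshold: float = 0.8,
) -> dict:
    """Full segmentation of one target: multi-atlas + appearance fusion.

    Returns the fused mask, both probability maps, and a QC flag raised when
    the fused mask's Dice against the thresholded atlas consensus falls below
    ``qc_dice_threshold`` (stand-in for visual inspection).
    """
    p_atlas = multiatlas_probability(target, atlases, config)
    if classifier is None:
        classifier = train_appearance_classifier(atlases)
    p_app = classifier.predict_probability(target)
    fused = fuse_and_threshold(p_atlas, p_app, weight, threshold)
    consensus = p_atlas >= 0.5
    qc = dice(fused, consensus) < qc_dice_threshold if consensus.any() else True
    return {
        "mask": fused,
        "p_atlas": p_atlas,
        "p_appearance": p_app,
        "qc_flag": bool(qc),
    }
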