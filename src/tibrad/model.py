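"""Elastic-net logistic classification with repeated cross-validated grid search.

The model minimizes the mean binomial negative log-likelihood plus the
elastic-net penalty

    lambda * [ alpha * sum|beta_j| + (1 - alpha)/2 * sum beta_j^2 ]

with the intercept unpenalized: ``alpha = 1`` is the lasso, ``alpha -> 0``
approaches ridge regression. Hyperparameters are selected by repeated
stratified k-fold cross-validation over an (alpha, lambda) grid, maximizing
the mean out-of-fold ROC AUC; features are standardized using training folds
only, so no scaling information leaks from held-out subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

VOI_SELECTIONS = ("All", "SBM", "MidM", "TBM", "SBL", "MidL", "TBL", "AllMedial")
MEDIAL_VOIS = ("SBM", "MidM", "TBM")


@dataclass(frozen=True)
class ModelSpec:
    mode: str = "combined"  # covariates | image | combined
    voi_selection: str = "All"
    alpha_grid: tuple[float, ...] = ()
    lambda_grid: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("covariates", "image", "combined"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.voi_selection not in VOI_SELECTIONS:
            raise ValueError(f"unknown VOI selection {self.voi_selection!r}")
        if any(not (0.0 <= a <= 1.0) for a in self.alpha_grid):
            raise ValueError("alpha values must lie in [0, 1]")
        if any(l <= 0 for l in self.lambda_grid):
            raise ValueError("lambda values must be positive")


@dataclass(frozen=True)
class CVProtocol:
    folds: int = 10
    repetitions: int = 100
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need k >= 2 folds")
        if self.repetitions < 1:
            raise ValueError("need at least one repetition")


@dataclass
class FitResult:
    coef: pd.Series
    intercept: float
    alpha: float
    lam: float
    converged: bool = True
    n_iter: int = 0
    cv_results: pd.DataFrame | None = None
    oof_scores: list[np.ndarray] = field(default_factory=list)
    oof_labels: list[np.ndarray] = field(default_factory=list)
    rep_roc_auc: list[float] = field(default_factory=list)
    rep_pr_auc: list[float] = field(default_factory=list)

    def top_coefficients(self, k: int = 5) -> pd.Series:
        """The k variables with largest |coefficient| in the fitted model."""
        return self.coef.reindex(self.coef.abs().sort_values(ascending=False).index[:k])


def build_grids(
    alpha_bounds: tuple[float, float, float] = (0.1, 1.0, 0.05),
    lambda_bounds: tuple[float, float, float] = (0.001, 0.15, 0.009),
) -> tuple[np.ndarray, np.ndarray]:
    """Inclusive arithmetic hyperparameter grids from (start, end, increment).

    The endpoint is included only when it lies on the grid within 1e-9; with
    the default bounds the alpha grid has 19 values ending at 1.0 and the
    lambda grid 17 values ending at 0.145 (0.15 is off-grid).
    """

    def seq(start: float, end: float, step: float) -> np.ndarray:
        if not (start < end) and not np.isclose(start, end):
            if start == end:
                return np.array([start])
            raise ValueError("start must not exceed end")
        if step <= 0:
            raise ValueError("increment must be positive")
        n = int(np.floor((end - start) / step + 1e-9)) + 1
        vals = start + step * np.arange(n)
        if vals.size == 0:
            raise ValueError("empty grid")
        return np.round(vals, 12)

    return seq(*alpha_bounds), seq(*lambda_bounds)


def build_design_matrix(
    cohort: pd.DataFrame,
    features: pd.DataFrame | None,
    spec: ModelSpec,
    outcome: str = "label_tfoa",
    drop_zero_variance: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble (X, y) for one model mode and VOI selection.

    Covariates mode: age and BMI. Image mode: features of the selected VOIs,
    plus the whole-bone shape features when the selection is ``All``.
    Combined: the union. Columns are returned unstandardized; scaling happens
    inside cross-validation on training folds only. Constant columns raise a
    named error by default; ``drop_zero_variance=True`` silently removes them
    (the only feature pre-filtering the classification pipeline performs).
    """
    cols: list[str] = []
    frames: list[pd.DataFrame] = []
    if spec.mode in ("covariates", "combined"):
        frames.append(cohort.set_index("subject_id")[["age", "bmi"]])
    if spec.mode in ("image", "combined"):
        if features is None:
            raise ValueError("image features required for this mode")
        if not cohort["subject_id"].isin(features.index).all():
            missing = cohort.loc[~cohort["subject_id"].isin(features.index), "subject_id"]
            raise ValueError(f"missing feature rows for subjects: {list(missing[:5])}")
        if spec.voi_selection == "All":
            vois: tuple[str, ...] = ("SBM", "MidM", "TBM", "SBL", "MidL", "TBL")
            include_shape = True
        elif spec.voi_selection == "AllMedial":
            vois = MEDIAL_VOIS
            include_shape = False
        else:
            vois = (spec.voi_selection,)
            include_shape = False
        img_cols = [
            c for c in features.columns if any(c.startswith(f"{v}_") for v in vois)
        ]
        if include_shape:
            img_cols += [c for c in features.columns if c.startswith("shape_")]
        frames.append(features.loc[cohort["subject_id"], img_cols])
    X = pd.concat([f.reset_index(drop=True) for f in frames], axis=1)
    X.index = cohort.index
    zero_var = X.columns[X.std(ddof=0) == 0]
    if len(zero_var):
        if drop_zero_variance:
            X = X.drop(columns=list(zero_var))
        else:
            raise ValueError(f"zero-variance predictor columns: {list(zero_var[:5])}")
    y = cohort[outcome].to_numpy(dtype=bool)
    return X, y


def penalty(beta: np.ndarray, alpha: float, lam: float) -> float:
    """Elastic-net penalty value; the intercept is excluded by the caller."""
    beta = np.asarray(beta, dtype=float)
    return float(lam * (alpha * np.abs(beta).sum() + (1.0 - alpha) / 2.0 * (beta**2).sum()))


def objective(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, intercept: float, alpha: float, lam: float
) -> float:
    """Mean binomial negative log-likelihood plus the elastic-net penalty."""
    eta = X @ beta + intercept
    nll = np.logaddexp(0.0, eta) - y * eta
    return float(nll.mean()) + penalty(beta, alpha, lam)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _solve_elastic_net(
    Xa: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    max_iter: int,
    tol: float,
    record_trace: bool = False,
) -> tuple[np.ndarray, float, int, list[float]]:
    """Monotone accelerated proximal-gradient (MFISTA) solver.

    The smooth part is the mean logistic NLL plus the ridge term; the L1 term
    enters through soft thresholding. The accepted iterate is always the best
    seen, so the recorded objective trace never increases. The intercept is
    an unpenalized extra coordinate.
    """
    n, p = Xa.shape
    Xe = np.column_stack([np.ones(n), Xa])
    yf = y.astype(float)
    # Lipschitz constant of the smooth gradient: ||Xe||^2 / (4n) + ridge
    s_max = np.linalg.norm(Xe, 2)
    L = s_max**2 / (4.0 * n) + lam * (1.0 - alpha)
    step = 1.0 / L
    thr = lam * alpha * step

    def smooth_grad(w: np.ndarray) -> np.ndarray:
        r = _sigmoid(Xe @ w) - yf
        g = Xe.T @ r / n
        g[1:] += lam * (1.0 - alpha) * w[1:]
        return g

    def obj(w: np.ndarray) -> float:
        return objective(Xa, yf, w[1:], w[0], alpha, lam)

    w = np.zeros(p + 1)
    z = w.copy()
    t = 1.0
    best = w.copy()
    f_best = obj(w)
    trace = [f_best] if record_trace else []
    n_iter = max_iter
    quiet = 0  # consecutive candidates indistinguishable from the incumbent
    for it in range(1, max_iter + 1):
        cand = z - step * smooth_grad(z)
        cand[1:] = np.sign(cand[1:]) * np.maximum(np.abs(cand[1:]) - thr, 0.0)
        f_cand = obj(cand)
        quiet = quiet + 1 if abs(f_cand - f_best) <= tol * max(1.0, abs(f_best)) else 0
        if f_cand < f_best:
            w_new = cand
            f_best = f_cand
        else:
            w_new = best  # monotone acceptance
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = w_new + (t / t_new) * (cand - w_new) + ((t - 1.0) / t_new) * (w_new - best)
        best = w_new
        t = t_new
        if record_trace:
            trace.append(f_best)
        if quiet >= 5:
            n_iter = it
            break
    return best, f_best, n_iter, trace


def fit_elastic_net(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    max_iter: int = 20000,
    tol: float = 1e-10,
    record_trace: bool = False,
) -> FitResult:
    """Single elastic-net logistic fit at fixed (alpha, lambda).

    Minimizes the mean binomial negative log-likelihood plus the elastic-net
    penalty with a deterministic monotone proximal-gradient solver; at
    ``alpha = 1`` this is the lasso, as ``alpha -> 0`` it approaches ridge
    regression. Raises with iteration diagnostics on non-convergence.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(np.shape(X)[1])]
    Xa = np.asarray(X, dtype=float)
    w, f_best, n_iter, trace = _solve_elastic_net(
        Xa, y, float(alpha), float(lam), max_iter, tol, record_trace
    )
    if n_iter >= max_iter:
        raise RuntimeError(
            f"elastic-net solver did not converge in {max_iter} iterations "
            f"(alpha={alpha}, lambda={lam}, final objective {f_best:.6g}); "
            "increase max_iter or loosen tol"
        )
    res = FitResult(
        coef=pd.Series(w[1:], index=names),
        intercept=float(w[0]),
        alpha=float(alpha),
        lam=float(lam),
        converged=True,
        n_iter=n_iter,
    )
    if record_trace:
        res.objective_trace = trace  # type: ignore[attr-defined]
    return res


def _check_protocol(y: np.ndarray, protocol: CVProtocol) -> None:
    pos = int(y.sum())
    neg = len(y) - pos
    if min(pos, neg) < protocol.folds:
        raise ValueError(
            f"minority class has {min(pos, neg)} subjects < k={protocol.folds} folds; "
            "use stratification with fewer folds"
        )


def grid_search_cv(
    X: pd.DataFrame,
    y: np.ndarray,
    spec: ModelSpec,
    protocol: CVProtocol,
    pool_mode: str = "averaged",
    return_fold_details: bool = False,
) -> FitResult:
    """Repeated stratified k-fold grid search over (alpha, lambda).

    For every grid pair, each repetition runs one stratified k-fold split;
    out-of-fold scores are pooled per repetition and the ROC AUC is averaged
    across repetitions (``pool_mode='pooled'`` instead concatenates scores
    over all repetitions before computing a single AUC). The pair with the
    best criterion is refit on all data (standardized on all rows) and the
    best pair's out-of-fold scores are retained for downstream evaluation.
    """
    y = np.asarray(y, dtype=int)
    _check_protocol(y, protocol)
    alphas = spec.alpha_grid or tuple(build_grids()[0])
    lams = spec.lambda_grid or tuple(build_grids()[1])
    n = len(y)

    # Pre-compute fold assignments per repetition (shared across grid pairs).
    splits_per_rep = []
    for r in range(protocol.repetitions):
        skf = StratifiedKFold(
            n_splits=protocol.folds, shuffle=True, random_state=(protocol.seed + r) % (2**31)
        )
        splits_per_rep.append(list(skf.split(np.zeros(n), y)))

    rows = []
    best = None
    fold_details: list[dict] = []
    for a in alphas:
        for lam in lams:
            rep_scores: list[np.ndarray] = []
            rep_aucs: list[float] = []
            for r, splits in enumerate(splits_per_rep):
                oof = np.full(n, np.nan)
                for tr, te in splits:
                    scaler = StandardScaler().fit(X.iloc[tr])
                    Xt = scaler.transform(X.iloc[tr])
                    Xv = scaler.transform(X.iloc[te])
                    w, _, _, _ = _solve_elastic_net(
                        Xt, y[tr], float(a), float(lam), max_iter=3000, tol=1e-7
                    )
                    oof[te] = _sigmoid(Xv @ w[1:] + w[0])
                    if return_fold_details:
                        fold_details.append(
                            {
                                "alpha": a,
                                "lambda": lam,
                                "rep": r,
                                "train_index": tr,
                                "scaler_mean": scaler.mean_.copy(),
                                "scaler_scale": scaler.scale_.copy(),
                                "coef": w[1:].copy(),
                            }
                        )
                rep_scores.append(oof)
                rep_aucs.append(roc_auc_score(y, oof))
            if pool_mode == "averaged":
                crit = float(np.mean(rep_aucs))
            else:
                crit = float(roc_auc_score(np.tile(y, len(rep_scores)), np.concatenate(rep_scores)))
            rows.append({"alpha": a, "lambda": lam, "mean_roc_auc": crit})
            if best is None or crit > best["crit"]:
                best = {
                    "alpha": a,
                    "lambda": lam,
                    "crit": crit,
                    "rep_scores": rep_scores,
                    "rep_aucs": rep_aucs,
                }
    assert best is not None

    scaler = StandardScaler().fit(X)
    final = fit_elastic_net(
        pd.DataFrame(scaler.transform(X), columns=X.columns), y, best["alpha"], best["lambda"]
    )
    final.cv_results = pd.DataFrame(rows)
    final.oof_scores = best["rep_scores"]
    final.oof_labels = [y.copy() for _ in best["rep_scores"]]
    final.rep_roc_auc = best["rep_aucs"]
    final.rep_pr_auc = [
        float(average_precision_score(y, s)) for s in best["rep_scores"]
    ]
    if return_fold_details:
        final.fold_details = fold_details  # type: ignore[attr-defined]
    return final
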