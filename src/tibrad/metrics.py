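"""ROC AUC, PR AUC, bootstrap confidence intervals, and report tables.

ROC AUC is the Mann-Whitney probability that a random positive outscores a
random negative (ties counted 1/2); PR AUC is the non-interpolated average
precision, whose chance level equals the class prevalence. Confidence
intervals use a stratified percentile bootstrap over subjects, which applies
uniformly to both metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

MODEL_MODES = ("covariates", "image", "combined")


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC AUC needs both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    labels = np.asarray(labels, dtype=bool)
    if not labels.any():
        raise ValueError("PR AUC needs at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class MetricWithCI:
    estimate: float
    ci_low: float
    ci_high: float
    method: str
    n_resamples: int
    seed: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("interval must bracket the estimate")

    def __str__(self) -> str:
        return f"{self.estimate:.2f} ({self.ci_low:.2f}–{self.ci_high:.2f})"


def bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], float],
    scores: np.ndarray,
    labels: np.ndarray,
    n_resamples: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> MetricWithCI:
    """Stratified percentile bootstrap CI for a score-based metric.

    Subjects are resampled with replacement within each class, so every
    resample retains both classes. Degenerate resamples are therefore
    impossible by construction; the estimate is computed on the original data.
    """
    if n_resamples < 100:
        raise ValueError("need at least 100 bootstrap resamples")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    est = metric(scores, labels)
    stats = np.empty(n_resamples)
    for b in range(n_resamples):
        idx = np.concatenate(
            [rng.choice(pos, size=pos.size), rng.choice(neg, size=neg.size)]
        )
        stats[b] = metric(scores[idx], labels[idx])
    lo, hi = np.percentile(stats, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    lo = min(float(lo), est)
    hi = max(float(hi), est)
    return MetricWithCI(est, lo, hi, "stratified percentile bootstrap", n_resamples, seed)


def evaluate_oof(
    oof_scores: list[np.ndarray],
    oof_labels: list[np.ndarray],
    n_resamples: int = 2000,
    seed: int = 0,
) -> dict[str, MetricWithCI]:
    """ROC and PR AUC with CIs from per-repetition out-of-fold scores.

    Scores are averaged across repetitions per subject before the bootstrap
    (each subject contributes once, so resampling subjects is well defined).
    """
    scores = np.mean(np.stack(oof_scores), axis=0)
    labels = np.asarray(oof_labels[0], dtype=bool)
    return {
        "roc_auc": bootstrap_ci(roc_auc, scores, labels, n_resamples, seed=seed),
        "pr_auc": bootstrap_ci(pr_auc, scores, labels, n_resamples, seed=seed + 1),
    }


def report_table(results: dict[str, dict[str, dict[str, MetricWithCI]]]) -> pd.DataFrame:
    """Assemble the VOI x model-mode performance table.

    ``results[voi][mode]`` holds ``{"roc_auc": ..., "pr_auc": ...}``. Rows are
    VOI selections, columns the three model modes x two metrics, formatted
    "est (lo-hi)"; missing cells become explicit "NA".
    """
    rows = {}
    for voi, by_mode in results.items():
        row = {}
        for mode in MODEL_MODES:
            cell = by_mode.get(mode, {})
            for met in ("roc_auc", "pr_auc"):
                key = f"{mode}_{met}"
                row[key] = str(cell[met]) if met in cell else "NA"
        rows[voi] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "VOI"
    return table


def roc_curve_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(np.asarray(labels, dtype=int), scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def pr_curve_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    from sklearn.metrics import precision_recall_curve

    prec, rec, thr = precision_recall_curve(np.asarray(labels, dtype=int), scores)
    return pd.DataFrame(
        {"recall": rec, "precision": prec, "threshold": np.append(thr, np.nan)}
    )


def save_table(table: pd.DataFrame, path_csv: str | Path, path_json: str | Path | None = None) -> None:
    table.to_csv(path_csv)
    if path_json is not None:
        Path(path_json).write_text(json.dumps(json.loads(table.to_json(orient="index")), indent=2))
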