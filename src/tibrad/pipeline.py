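"""End-to-end pipeline orchestration with config validation and manifests.

Stages (simulate -> segment -> voi -> features -> train -> evaluate)
communicate through files only (NIfTI/CSV/JSON) under the run's output
directory, so any stage can be re-run from its predecessors' outputs. A JSON
manifest records the validated config, seeds, per-stage output checksums and
timings; two runs with the same config and seed produce identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from . import segmentation as seg
from .core import ImageVolume, load_mask, save_mask
from .features import FeatureConfig, extract_all
from .metrics import evaluate_oof, report_table, save_table
from .moaks import records_to_frame, summarize_labels
from .phantom import (
    PhantomParams,
    generate_cohort,
    generate_moaks_records,
    generate_tibia_phantom,
    phantom_for_row,
)
from .model import CVProtocol, ModelSpec, build_design_matrix, build_grids, grid_search_cv
from .voi import extract_vois

STAGES = ("simulate", "segment", "voi", "features", "train", "evaluate")


class PhantomConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    grid_shape: tuple[int, int, int] = (72, 72, 96)
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    noise_sd: float = 2.0
    oa_texture_corr_len_mm: float = 2.0
    control_texture_corr_len_mm: float = 0.5
    oa_irregularity_amp: float = 0.25

    def to_params(self, seed: int = 0) -> PhantomParams:
        from .phantom import ClassEffect

        return PhantomParams(
            grid_shape=self.grid_shape,
            spacing_mm=self.spacing_mm,
            noise_sd=self.noise_sd,
            control=ClassEffect(texture_corr_len_mm=self.control_texture_corr_len_mm),
            oa=ClassEffect(
                texture_corr_len_mm=self.oa_texture_corr_len_mm,
                surface_irregularity_amp=self.oa_irregularity_amp,
            ),
            seed=seed,
        )


class CVConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    folds: int = 10
    repetitions: int = 100
    alpha_bounds: tuple[float, float, float] = (0.1, 1.0, 0.05)
    lambda_bounds: tuple[float, float, float] = (0.001, 0.15, 0.009)

    @field_validator("folds")
    @classmethod
    def _k(cls, v: int) -> int:
        if v < 2:
            raise ValueError("folds must be >= 2")
        return v

    @field_validator("repetitions")
    @classmethod
    def _r(cls, v: int) -> int:
        if v < 1:
            raise ValueError("repetitions must be >= 1")
        return v


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    outdir: str = "runs/default"
    n: int = 60
    prevalence: float = 0.114
    voi_height_mm: float = 10.0
    central_fraction: float = 0.8
    laterality: Literal["right", "left"] = "right"
    segmentation_mode: Literal["multiatlas", "truth"] = "multiatlas"
    n_atlases: int = 3
    fusion_weight: float = 0.5
    fusion_threshold: float = 0.5
    modes: tuple[str, ...] = ("covariates", "image", "combined")
    voi_selection: str = "All"
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    cv: CVConfig = Field(default_factory=CVConfig)

    @field_validator("stages")
    @classmethod
    def _stages(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        bad = [s for s in v if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        return v


def validate_config(raw: dict | str | Path | None) -> RunConfig:
    """Validate a raw config mapping (or YAML/JSON file); fill defaults.

    Schema violations list every offending key; unknown keys are rejected.
    """
    if raw is None:
        raw = {}
    if isinstance(raw, (str, Path)):
        raw = yaml.safe_load(Path(raw).read_text()) or {}
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        offenders = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ValueError(f"invalid run configuration: {offenders}") from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _subject_seed(global_seed: int, i: int) -> int:
    # documented counter scheme: one stream per subject index
    return int((global_seed * 1000003 + i) % (2**31 - 1))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; return (and write) the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.model_dump(), "stages": {}}
    params = config.phantom.to_params()

    def record(stage: str, t0: float, outputs: list[Path]) -> None:
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in sorted(outputs)},
        }

    def require(path: Path, producer: str) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"missing input {path}; run the {producer!r} stage first"
            )
        return path

    if "simulate" in config.stages:
        t0 = time.time()
        outputs = []
        cohort = generate_cohort(config.n, config.prevalence, params, config.seed)
        cohort_path = out / "cohort.csv"
        cohort.to_csv(cohort_path, index=False)
        outputs.append(cohort_path)
        moaks = records_to_frame(generate_moaks_records(cohort, config.seed))
        moaks_path = out / "moaks.csv"
        moaks.to_csv(moaks_path, index=False)
        outputs.append(moaks_path)
        pdir = out / "phantoms"
        pdir.mkdir(exist_ok=True)
        for _, row in cohort.iterrows():
            vol, mask = phantom_for_row(row, params)
            vp = pdir / f"{row['subject_id']}_volume.nii.gz"
            mp = pdir / f"{row['subject_id']}_mask.nii.gz"
            vol.to_nifti(vp)
            save_mask(mask, vol.spacing, mp)
            outputs.extend([vp, mp])
        record("simulate", t0, outputs)

    if "segment" in config.stages:
        t0 = time.time()
        outputs = []
        cohort = pd.read_csv(require(out / "cohort.csv", "simulate"))
        sdir = out / "segmentations"
        sdir.mkdir(exist_ok=True)
        dice_rows = []
        atlases = None
        classifier = None
        if config.segmentation_mode == "multiatlas":
            atlases = []
            for j in range(config.n_atlases):
                ap = dataclasses.replace(params, seed=_subject_seed(config.seed + 7919, j))
                atlases.append(generate_tibia_phantom(ap, False))
            classifier = seg.train_appearance_classifier(atlases, seed=config.seed)
        for _, row in cohort.iterrows():
            sid = row["subject_id"]
            vol = ImageVolume.from_nifti(require(out / "phantoms" / f"{sid}_volume.nii.gz", "simulate"))
            truth, _ = load_mask(out / "phantoms" / f"{sid}_mask.nii.gz")
            if config.segmentation_mode == "truth":
                pred = truth
                qc = False
            else:
                res = seg.segment_tibia(
                    vol, atlases, classifier,
                    weight=config.fusion_weight, threshold=config.fusion_threshold,
                )
                pred, qc = res["mask"], res["qc_flag"]
            mp = sdir / f"{sid}_pred.nii.gz"
            save_mask(pred, vol.spacing, mp)
            outputs.append(mp)
            dice_rows.append({"subject_id": sid, "dice": seg.dice(pred, truth), "qc_flag": qc})
        dice_path = out / "dice.csv"
        pd.DataFrame(dice_rows).to_csv(dice_path, index=False)
        outputs.append(dice_path)
        record("segment", t0, outputs)

    if "voi" in config.stages:
        t0 = time.time()
        outputs = []
        cohort = pd.read_csv(require(out / "cohort.csv", "simulate"))
        vdir = out / "vois"
        vdir.mkdir(exist_ok=True)
        for _, row in cohort.iterrows():
            sid = row["subject_id"]
            mask, spacing = load_mask(require(out / "segmentations" / f"{sid}_pred.nii.gz", "segment"))
            vois = extract_vois(
                mask, spacing,
                voi_height_mm=config.voi_height_mm,
                central_fraction=config.central_fraction,
                laterality=config.laterality,
            )
            vp = vdir / f"{sid}_vois.json"
            vois.to_json(vp)
            outputs.append(vp)
        record("voi", t0, outputs)

    if "features" in config.stages:
        t0 = time.time()
        cohort = pd.read_csv(require(out / "cohort.csv", "simulate"))
        fc = FeatureConfig()
        rows = {}
        from .voi import VOISet

        for _, row in cohort.iterrows():
            sid = row["subject_id"]
            vol = ImageVolume.from_nifti(require(out / "phantoms" / f"{sid}_volume.nii.gz", "simulate"))
            mask, _ = load_mask(require(out / "segmentations" / f"{sid}_pred.nii.gz", "segment"))
            vois = VOISet.from_json(require(out / "vois" / f"{sid}_vois.json", "voi"))
            rows[sid] = extract_all(vol, mask, vois, fc).values
        feats = pd.DataFrame(rows).T
        feats.index.name = "subject_id"
        fpath = out / "features.csv"
        feats.to_csv(fpath)
        record("features", t0, [fpath])

    if "train" in config.stages:
        t0 = time.time()
        outputs = []
        cohort = pd.read_csv(require(out / "cohort.csv", "simulate"))
        feats = pd.read_csv(require(out / "features.csv", "features"), index_col="subject_id")
        alphas, lams = build_grids(config.cv.alpha_bounds, config.cv.lambda_bounds)
        protocol = CVProtocol(
            folds=config.cv.folds, repetitions=config.cv.repetitions, seed=config.seed
        )
        for mode in config.modes:
            spec = ModelSpec(
                mode=mode, voi_selection=config.voi_selection,
                alpha_grid=tuple(alphas), lambda_grid=tuple(lams),
            )
            X, y = build_design_matrix(cohort, feats, spec, drop_zero_variance=True)
            fit = grid_search_cv(X, y, spec, protocol)
            oof = pd.DataFrame(
                {f"rep{r}": s for r, s in enumerate(fit.oof_scores)}
            )
            oof.insert(0, "label", y.astype(int))
            opath = out / f"oof_{mode}.csv"
            oof.to_csv(opath, index=False)
            outputs.append(opath)
            mpath = out / f"model_{mode}.json"
            mpath.write_text(
                json.dumps(
                    {
                        "mode": mode,
                        "alpha": fit.alpha,
                        "lambda": fit.lam,
                        "mean_cv_roc_auc": float(np.mean(fit.rep_roc_auc)),
                        "top5_coefficients": fit.top_coefficients(5).round(6).to_dict(),
                    },
                    indent=2,
                )
            )
            outputs.append(mpath)
        record("train", t0, outputs)

    if "evaluate" in config.stages:
        t0 = time.time()
        outputs = []
        table_input = {config.voi_selection: {}}
        for mode in config.modes:
            oof = pd.read_csv(require(out / f"oof_{mode}.csv", "train"))
            labels = oof["label"].to_numpy(dtype=bool)
            scores = [oof[c].to_numpy() for c in oof.columns if c.startswith("rep")]
            table_input[config.voi_selection][mode] = evaluate_oof(
                scores, [labels] * len(scores), n_resamples=500, seed=config.seed
            )
        table = report_table(table_input)
        save_table(table, out / "results.csv", out / "results.json")
        outputs.extend([out / "results.csv", out / "results.json"])
        cohort = pd.read_csv(out / "cohort.csv")
        summary = summarize_labels(cohort[["label_tfoa", "label_cartilage", "label_osteophyte", "label_bml"]].astype(bool))
        summary.to_csv(out / "label_summary.csv", index=False)
        outputs.append(out / "label_summary.csv")
        record("evaluate", t0, outputs)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
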