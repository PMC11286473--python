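"""Run configuration and end-to-end orchestration.

``RunConfig`` validates a YAML/dict configuration (unknown keys rejected,
units and signs checked) whose numeric defaults are the pipeline's
canonical thresholds: Tmax > 6 s (ischemic), ADC < 620e-6 mm^2/s
(infarct), vein window 90-300 ppb, SvO2 < 0.7 (hypoxic), t-test alpha
0.05, train fraction 0.7.

``run_all`` executes simulate -> segment -> extract -> select -> evaluate,
persisting every intermediate artifact (NIfTI masks, feature and
selection CSVs, the evaluation report and a JSON manifest of all settings
and seeds).  A stage failure raises :class:`StageError` naming the stage;
artifacts of completed stages are left in place.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from perfrad import workflows
from perfrad.evaluation import CLASSIFIER_KINDS, run_experiment_matrix, split_cohort
from perfrad.radiomics.extract import FEATURE_CLASSES, cohort_feature_table
from perfrad.radiomics.filters import FilterSpec, default_filter_bank
from perfrad.selection import GROUP_NAMES, assemble_group, group_regions, select_region_features, standardize
from perfrad.synthetic import GOOD, CohortConfig, generate_cohort, save_subject


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortSection(_Strict):
    n_good: int = 45
    n_poor: int = 45
    volume_shape: tuple[int, int, int] = (48, 48, 14)
    voxel_spacing: tuple[float, float, float] = (4.0, 4.0, 5.0)
    lesion_radius_range: tuple[float, float] = (4.0, 7.0)
    noise_scale: float = 1.0      # multiplies the per-map noise SDs
    chi_noise_sd: float = 5.0
    boundary_taper_sigma: float = 1.0

    def build(self, seed: int) -> CohortConfig:
        from perfrad.synthetic import DEFAULT_NOISE_SD

        return CohortConfig(
            n_good=self.n_good, n_poor=self.n_poor,
            volume_shape=tuple(self.volume_shape),
            voxel_spacing=tuple(self.voxel_spacing),
            lesion_radius_range=tuple(self.lesion_radius_range),
            noise_sd={k: v * self.noise_scale for k, v in DEFAULT_NOISE_SD.items()},
            chi_noise_sd=self.chi_noise_sd,
            boundary_taper_sigma=self.boundary_taper_sigma,
            seed=seed,
        )


class ThresholdSection(_Strict):
    tmax_s: float = 6.0
    adc_mm2_s: float = 620e-6
    vein_low_ppb: float = 90.0
    vein_high_ppb: float = 300.0
    svo2: float = 0.7

    @field_validator("tmax_s", "adc_mm2_s", "vein_low_ppb", "vein_high_ppb", "svo2")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"threshold {info.field_name} must be positive, got {v}")
        return v


class ExtractionSection(_Strict):
    filter_bank: str = "default"  # default | original
    feature_classes: tuple[str, ...] = FEATURE_CLASSES
    bin_width: float = 25.0
    min_voxels: int = 10

    @field_validator("feature_classes")
    @classmethod
    def _known(cls, v):
        bad = set(v) - set(FEATURE_CLASSES)
        if bad:
            raise ValueError(f"unknown feature classes {sorted(bad)}")
        return v

    def filters(self) -> list[FilterSpec]:
        if self.filter_bank == "default":
            return default_filter_bank()
        if self.filter_bank == "original":
            return [FilterSpec("original")]
        raise ValueError(f"unknown filter bank {self.filter_bank!r}")


class SelectionSection(_Strict):
    alpha: float = 0.05
    cv_folds: int = 5
    equal_var: bool = True


class EvaluationSection(_Strict):
    train_ratio: float = 0.7
    groups: tuple[str, ...] = GROUP_NAMES
    classifiers: tuple[str, ...] = CLASSIFIER_KINDS

    @field_validator("groups")
    @classmethod
    def _valid_groups(cls, v):
        bad = [g for g in v if g not in GROUP_NAMES]
        if bad:
            raise ValueError(f"unknown group name(s) {bad}; valid: {sorted(GROUP_NAMES)}")
        return v

    @field_validator("classifiers")
    @classmethod
    def _valid_clf(cls, v):
        bad = [c for c in v if c not in CLASSIFIER_KINDS]
        if bad:
            raise ValueError(f"unknown classifier(s) {bad}; panel: {CLASSIFIER_KINDS}")
        return v


class RunConfig(_Strict):
    """Validated end-to-end run configuration with study defaults."""

    out_dir: str = "perfrad_run"
    seed: int = 0
    mask_source: str = "truth"  # truth | segmented
    cohort: CohortSection = Field(default_factory=CohortSection)
    thresholds: ThresholdSection = Field(default_factory=ThresholdSection)
    extraction: ExtractionSection = Field(default_factory=ExtractionSection)
    selection: SelectionSection = Field(default_factory=SelectionSection)
    evaluation: EvaluationSection = Field(default_factory=EvaluationSection)
    log_level: str = "INFO"

    @field_validator("mask_source")
    @classmethod
    def _src(cls, v):
        if v not in ("truth", "segmented"):
            raise ValueError("mask_source must be 'truth' or 'segmented'")
        return v


def validate_config(source) -> RunConfig:
    """Build a RunConfig from a YAML file path, YAML text, or dict.

    Missing keys get the study defaults; unknown keys are rejected with
    the offending field named.  An empty file yields the full default
    configuration.
    """
    if isinstance(source, RunConfig):
        return source
    if isinstance(source, dict):
        return RunConfig(**source)
    path = Path(source)
    text = path.read_text() if path.exists() else str(source)
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration must be a YAML mapping")
    return RunConfig(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage: {stage}] {cause}")
        self.stage = stage
        self.cause = cause


def _save_mask(mask, spacing, path):
    import nibabel as nib

    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), path)


def run_all(config: RunConfig | dict | str, save_volumes: bool = True) -> dict:
    """Execute all five stages, persisting intermediates under ``out_dir``.

    Returns a dict with the evaluation report and the paths of every
    artifact written.  Reruns with an identical configuration reproduce
    byte-identical tables.
    """
    config = validate_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    # stage 1: simulate
    try:
        cohort = generate_cohort(config.cohort.build(config.seed))
        manifest = pd.DataFrame(
            [{"subject_id": s.subject_id, "label": s.label, "seed": s.seed,
              "affected_hemisphere": s.affected_hemisphere} for s in cohort]
        )
        if save_volumes:
            sub_dir = out / "subjects"
            for s in cohort:
                save_subject(s, sub_dir)
        manifest.to_csv(out / "manifest.csv", index=False)
        artifacts["manifest"] = str(out / "manifest.csv")
    except Exception as exc:
        raise StageError("simulate", exc) from exc

    # stage 2: segment
    try:
        from perfrad.svo2 import SvO2Params

        params = SvO2Params(
            svo2_ref=config.thresholds.svo2,
            vein_low=config.thresholds.vein_low_ppb,
            vein_high=config.thresholds.vein_high_ppb,
        )
        masks = (
            {s.subject_id: {**workflows.segment_subject(s, params)} for s in cohort}
            if config.mask_source == "segmented"
            else {s.subject_id: dict(s.truth_masks) for s in cohort}
        )
        mask_dir = out / "masks"
        mask_dir.mkdir(exist_ok=True)
        for s in cohort:
            for kind, m in masks[s.subject_id].items():
                _save_mask(m, s.voxel_spacing, mask_dir / f"{s.subject_id}_{kind}.nii.gz")
        artifacts["masks"] = str(mask_dir)
    except Exception as exc:
        raise StageError("segment", exc) from exc

    # stage 3: extract
    try:
        filters = config.extraction.filters()
        feat_dir = out / "features"
        feat_dir.mkdir(exist_ok=True)
        subject_ids = [s.subject_id for s in cohort]
        radiomics_raw, flagged = {}, set()
        for region in workflows.REGIONS:
            table, bad = cohort_feature_table(
                cohort, {sid: masks[sid][region] for sid in subject_ids}, region,
                filters=filters, classes=config.extraction.feature_classes,
                bin_width=config.extraction.bin_width,
                min_voxels=config.extraction.min_voxels,
            )
            table.to_csv(feat_dir / f"{region}.csv")
            radiomics_raw[region] = table
            flagged.update(bad)
        (feat_dir / "settings.json").write_text(json.dumps({
            "filter_bank": config.extraction.filter_bank,
            "feature_classes": list(config.extraction.feature_classes),
            "bin_width": config.extraction.bin_width,
            "flagged_subjects": sorted(flagged),
        }, indent=2))
        artifacts["features"] = str(feat_dir)
    except Exception as exc:
        raise StageError("extract", exc) from exc

    # stage 4: select
    try:
        keep = [sid for sid in subject_ids if sid not in flagged]
        y = pd.Series([0 if s.label == GOOD else 1 for s in cohort], index=subject_ids).loc[keep]
        train_idx, test_idx = split_cohort(y.to_numpy(), ratio=config.evaluation.train_ratio, seed=config.seed)
        train_rows = y.index[train_idx]
        sel_dir = out / "selection"
        sel_dir.mkdir(exist_ok=True)
        radiomics_sel = {}
        for region, table in radiomics_raw.items():
            std, rep = select_region_features(
                table.loc[keep], y, train_rows,
                alpha=config.selection.alpha, cv_folds=config.selection.cv_folds,
                seed=config.seed, equal_var=config.selection.equal_var,
            )
            rep.table.to_csv(sel_dir / f"{region}_report.csv")
            radiomics_sel[region] = std[rep.retained]
        params_std = {}
        for region in workflows.REGIONS:
            raw = workflows.cohort_parameter_table(cohort, masks, region).loc[keep]
            params_std[region], _ = standardize(raw, train_rows)
            raw.to_csv(sel_dir / f"{region}_parameters.csv")
        artifacts["selection"] = str(sel_dir)
    except Exception as exc:
        raise StageError("select", exc) from exc

    # stage 5: evaluate
    try:
        group_tables = {g: assemble_group(g, radiomics_sel, params_std)
                        for g in config.evaluation.groups}
        report = run_experiment_matrix(
            group_tables, y.to_numpy(), seed=config.seed,
            classifiers=config.evaluation.classifiers,
            split=(train_idx, test_idx),
        )
        report.to_csv(out / "report.csv", index=False)
        report.to_json(out / "report.json", orient="records", indent=2)
        (out / "run_manifest.json").write_text(json.dumps({
            "config": config.model_dump(),
            "n_subjects": len(cohort),
            "n_train": int(len(train_idx)),
            "n_test": int(len(test_idx)),
            "flagged_subjects": sorted(flagged),
        }, indent=2, default=str))
        artifacts["report"] = str(out / "report.csv")
        artifacts["run_manifest"] = str(out / "run_manifest.json")
    except Exception as exc:
        raise StageError("evaluate", exc) from exc

    return {"report": report, "artifacts": artifacts, "labels": y,
            "group_tables": group_tables}
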