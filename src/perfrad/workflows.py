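"""End-to-end study workflows over synthetic cohorts.

These functions chain the pipeline stages in memory: generate a cohort,
obtain region masks (ground truth or recomputed by the segmentation
operators), extract radiomics features and regional perfusion parameters,
run the selection chain on the training rows, assemble the named
experimental groups and evaluate the classifier panel on one shared
stratified split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from perfrad.evaluation import CLASSIFIER_KINDS, run_experiment_matrix, split_cohort
from perfrad.radiomics.extract import FEATURE_CLASSES, cohort_feature_table
from perfrad.radiomics.filters import FilterSpec, default_filter_bank
from perfrad.segmentation import (
    PERFUSION_MAPS,
    compute_adc,
    region_mean_parameters,
    segment_infarct,
    segment_ischemic,
)
from perfrad.selection import GROUP_NAMES, assemble_group, group_regions, select_region_features, standardize
from perfrad.svo2 import (
    SvO2Params,
    affected_hemisphere_of,
    compute_unit_svo2,
    partition_hemisphere_grid,
    segment_hypoxic,
    upright_align,
)
from perfrad.synthetic import GOOD, CohortConfig, SubjectPhantom, generate_cohort, mirror_lr

REGIONS = ("ischemic", "infarct", "hypoxic")


def segment_subject(subject: SubjectPhantom, svo2_params: SvO2Params | None = None) -> dict:
    """Recompute the three region masks from a subject's volumes."""
    svo2_params = svo2_params or SvO2Params()
    ischemic = segment_ischemic(subject.maps["Tmax"], subject.brain_mask)
    adc = compute_adc(subject.dwi_b0, subject.dwi_b1000)
    infarct = segment_infarct(adc, subject.brain_mask)
    chi_al, mask_al, record = upright_align(subject.chi, subject.brain_mask)
    partition = partition_hemisphere_grid(mask_al, grid=svo2_params.grid)
    grid = compute_unit_svo2(chi_al, partition, svo2_params)
    if ischemic.mask.any():
        affected = affected_hemisphere_of(ischemic.mask, partition.midline_x)
    else:
        affected = subject.affected_hemisphere
    hypoxic_aligned = segment_hypoxic(grid, mask_al, affected)
    hypoxic_mask = record.apply_inverse(hypoxic_aligned.mask.astype(np.uint8)) > 0.5
    hypoxic = hypoxic_aligned
    hypoxic.mask = hypoxic_mask & subject.brain_mask
    return {"ischemic": ischemic.mask, "infarct": infarct.mask, "hypoxic": hypoxic.mask}


def cohort_masks(cohort, source: str = "truth") -> dict:
    """Per-subject region masks: generator ground truth or recomputed."""
    if source == "truth":
        return {s.subject_id: dict(s.truth_masks) for s in cohort}
    if source == "segmented":
        return {s.subject_id: segment_subject(s) for s in cohort}
    raise ValueError(f"unknown mask source {source!r}")


def cohort_parameter_table(cohort, masks: dict, region: str) -> pd.DataFrame:
    """Four regional perfusion-parameter means per subject for one region."""
    rows = {}
    for subj in cohort:
        params = region_mean_parameters(subj.maps, masks[subj.subject_id][region])
        rows[subj.subject_id] = {f"{region}__{m}": params.means[m] for m in PERFUSION_MAPS}
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class StudyResult:
    """Everything one synthetic study run produced."""

    labels: pd.Series
    split: tuple
    eval_report: pd.DataFrame
    selection_reports: dict = field(default_factory=dict)
    group_tables: dict = field(default_factory=dict)
    flagged_subjects: list = field(default_factory=list)

    def best_auc(self, group: str) -> float:
        sub = self.eval_report[self.eval_report.group == group]
        return float(sub["AUC"].max())

    def aucs(self, group: str) -> pd.Series:
        sub = self.eval_report[self.eval_report.group == group]
        return sub.set_index("classifier")["AUC"]


def run_study(
    config: CohortConfig | None = None,
    cohort=None,
    groups=GROUP_NAMES,
    regions=None,
    mask_source: str = "truth",
    filters: list[FilterSpec] | None = None,
    classes=FEATURE_CLASSES,
    bin_width: float = 25.0,
    alpha: float = 0.05,
    cv_folds: int = 5,
    split_ratio: float = 0.7,
    seed: int = 0,
    classifiers=CLASSIFIER_KINDS,
    permute_labels: bool = False,
    extra_radiomics_masks: dict | None = None,
) -> StudyResult:
    """Run the full comparative study on one synthetic cohort.

    ``groups`` restricts which experimental groups are evaluated (regions
    are only processed if some group needs them).  ``permute_labels``
    shuffles the class labels before splitting — the null calibration.
    ``extra_radiomics_masks`` maps an extra pseudo-region label to
    ``{subject_id: mask}`` and adds a ``<Label>_radiomics`` group (used
    for mis-localized control regions).
    """
    if cohort is None:
        cohort = generate_cohort(config or CohortConfig(seed=seed))
    subject_ids = [s.subject_id for s in cohort]
    y = pd.Series([0 if s.label == GOOD else 1 for s in cohort], index=subject_ids)
    if permute_labels:
        rng = np.random.default_rng(seed + 10_000)
        y = pd.Series(rng.permutation(y.to_numpy()), index=subject_ids)

    needed = set()
    for g in groups:
        regs, _ = group_regions(g)
        needed.update(regs)
    if regions is not None:
        needed &= set(regions)
    needed = [r for r in REGIONS if r in needed]

    masks = cohort_masks(cohort, source=mask_source)
    if filters is None:
        filters = default_filter_bank()

    # feature tables per region; subjects whose region is too small are flagged
    radiomics_raw, flagged = {}, set()
    for region in needed:
        table, bad = cohort_feature_table(
            cohort, {sid: masks[sid][region] for sid in subject_ids}, region,
            filters=filters, classes=classes, bin_width=bin_width,
        )
        radiomics_raw[region] = table
        flagged.update(bad)
    extra_raw = {}
    for label, mask_by_subject in (extra_radiomics_masks or {}).items():
        table, bad = cohort_feature_table(
            cohort, mask_by_subject, label.lower(),
            filters=filters, classes=classes, bin_width=bin_width,
        )
        extra_raw[label] = table
        flagged.update(bad)

    keep = [sid for sid in subject_ids if sid not in flagged]
    y = y.loc[keep]
    train_idx, test_idx = split_cohort(y.to_numpy(), ratio=split_ratio, seed=seed)
    train_rows = y.index[train_idx]

    selection_reports, radiomics_sel = {}, {}
    for region, table in radiomics_raw.items():
        std, rep = select_region_features(
            table.loc[keep], y, train_rows, alpha=alpha, cv_folds=cv_folds, seed=seed,
        )
        selection_reports[region] = rep
        radiomics_sel[region] = std[rep.retained]

    params_std = {}
    for region in needed:
        raw = cohort_parameter_table(cohort, masks, region).loc[keep]
        params_std[region], _ = standardize(raw, train_rows)

    group_tables = {}
    for g in groups:
        group_tables[g] = assemble_group(g, radiomics_sel, params_std)
    for label, table in extra_raw.items():
        std, rep = select_region_features(
            table.loc[keep], y, train_rows, alpha=alpha, cv_folds=cv_folds, seed=seed,
        )
        selection_reports[label] = rep
        group_tables[f"{label}_radiomics"] = std[rep.retained]

    report = run_experiment_matrix(
        group_tables, y.to_numpy(), ratio=split_ratio, seed=seed,
        classifiers=classifiers, split=(train_idx, test_idx),
    )
    return StudyResult(
        labels=y, split=(train_idx, test_idx), eval_report=report,
        selection_reports=selection_reports, group_tables=group_tables,
        flagged_subjects=sorted(flagged),
    )


def mirrored_control_masks(cohort) -> dict:
    """Mis-localized control region: the ischemic mask mirrored into the
    healthy hemisphere (no class effect was planted there)."""
    return {s.subject_id: mirror_lr(s.truth_masks["ischemic"]) & s.brain_mask for s in cohort}
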