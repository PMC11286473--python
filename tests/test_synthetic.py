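"""Generator contracts: determinism, anatomy invariants, statistical fidelity."""

import numpy as np
import pandas as pd
import pytest

from conftest import noise_free_config
from perfrad.segmentation import compute_adc, segment_infarct, segment_ischemic
from perfrad.synthetic import (
    TABLE_CLASS_EFFECTS,
    CohortConfig,
    generate_cohort,
    generate_subject,
    load_subject,
    save_subject,
    summarize_cohort,
)


def _volumes(s):
    yield from s.maps.values()
    yield s.dwi_b0
    yield s.dwi_b1000
    yield s.chi


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = generate_subject(CohortConfig(), "poor", seed=42)
        b = generate_subject(CohortConfig(), "poor", seed=42)
        for va, vb in zip(_volumes(a), _volumes(b)):
            np.testing.assert_array_equal(va, vb)
        for k in a.truth_masks:
            np.testing.assert_array_equal(a.truth_masks[k], b.truth_masks[k])

    def test_different_master_seeds_differ(self):
        a = generate_cohort(CohortConfig(n_good=1, n_poor=1, seed=0))
        b = generate_cohort(CohortConfig(n_good=1, n_poor=1, seed=99))
        assert any(
            not np.array_equal(va, vb)
            for sa, sb in zip(a, b)
            for va, vb in zip(_volumes(sa), _volumes(sb))
        )


class TestCohortAssembly:
    def test_cohort_sizes_and_labels(self):
        cohort = generate_cohort(CohortConfig(n_good=3, n_poor=2, seed=1))
        assert len(cohort) == 5
        assert sum(s.label == "good" for s in cohort) == 3
        assert sum(s.label == "poor" for s in cohort) == 2

    def test_single_subject_cohort(self):
        cohort = generate_cohort(CohortConfig(n_good=1, n_poor=0, seed=1))
        assert len(cohort) == 1 and cohort[0].label == "good"

    def test_zero_subjects_rejected(self):
        with pytest.raises(ValueError, match="zero subjects"):
            generate_cohort(CohortConfig(n_good=0, n_poor=0))

    def test_bad_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            generate_subject(CohortConfig(), "mediocre", seed=0)

    def test_oversized_lesion_rejected(self):
        with pytest.raises(ValueError, match="lesion"):
            CohortConfig(volume_shape=(16, 48, 14), lesion_radius_range=(4.0, 7.0))


class TestAnatomyInvariants:
    def test_masks_inside_brain_and_unilateral(self, default_subject):
        s = default_subject
        mid = s.brain_mask.shape[0] // 2
        for kind, m in s.truth_masks.items():
            assert not (m & ~s.brain_mask).any(), kind
        xs = np.nonzero(s.truth_masks["ischemic"])[0]
        assert (xs < mid).all() or (xs >= mid).all()
        assert (s.truth_masks["infarct"] & ~s.truth_masks["ischemic"]).sum() == 0

    def test_dwi_pair_physical(self, default_subject):
        s = default_subject
        inb = s.brain_mask
        assert (s.dwi_b1000[inb] <= s.dwi_b0[inb]).all()
        for vol in s.maps.values():
            assert (vol >= 0).all()

    def test_infarct_mask_consistent_with_recomputed_adc(self, default_subject):
        # construction guarantee: thresholding the ADC recomputed from the
        # generated DWI pair reproduces the truth infarct mask voxelwise
        s = default_subject
        adc = compute_adc(s.dwi_b0, s.dwi_b1000)
        rec = segment_infarct(adc, s.brain_mask)
        np.testing.assert_array_equal(rec.mask, s.truth_masks["infarct"])

    def test_noise_free_threshold_recovery(self, clean_subject):
        s = clean_subject
        np.testing.assert_array_equal(
            segment_ischemic(s.maps["Tmax"], s.brain_mask).mask,
            s.truth_masks["ischemic"],
        )
        np.testing.assert_array_equal(
            segment_infarct(compute_adc(s.dwi_b0, s.dwi_b1000), s.brain_mask).mask,
            s.truth_masks["infarct"],
        )


class TestStatisticalFidelity:
    def test_all_region_means_within_3se(self, fidelity_cohort):
        summary = summarize_cohort(fidelity_cohort)
        assert summary.n_missing.sum() == 0
        for _, r in summary.iterrows():
            mean, sd = TABLE_CLASS_EFFECTS[r.region][r["map"]][r["class"]]
            se = sd / np.sqrt(r.n)
            assert abs(r["mean"] - mean) <= 3 * se, (r.region, r["map"], r["class"])

    def test_ischemic_tmax_means_within_2se(self, fidelity_cohort):
        summary = summarize_cohort(fidelity_cohort, regions=("ischemic",))
        rows = summary[summary["map"] == "Tmax"].set_index("class")
        for cls, target in (("good", 6.24), ("poor", 12.18)):
            sd = TABLE_CLASS_EFFECTS["ischemic"]["Tmax"][cls][1]
            se = sd / np.sqrt(rows.loc[cls, "n"])
            assert abs(rows.loc[cls, "mean"] - target) <= 2 * se

    def test_infarct_tmax_means_within_2se(self, fidelity_cohort):
        summary = summarize_cohort(fidelity_cohort, regions=("infarct",))
        rows = summary[summary["map"] == "Tmax"].set_index("class")
        for cls, target in (("good", 5.80), ("poor", 13.99)):
            sd = TABLE_CLASS_EFFECTS["infarct"]["Tmax"][cls][1]
            se = sd / np.sqrt(rows.loc[cls, "n"])
            assert abs(rows.loc[cls, "mean"] - target) <= 2 * se

    def test_no_effect_null_shows_no_class_difference(self):
        from scipy.stats import ttest_ind

        effects = {
            region: {name: {c: per_class["good"] for c in ("good", "poor")}
                     for name, per_class in per_map.items()}
            for region, per_map in TABLE_CLASS_EFFECTS.items()
        }
        cohort = generate_cohort(CohortConfig(n_good=30, n_poor=30, seed=77, class_effects=effects))
        means = {name: {"good": [], "poor": []} for name in cohort[0].maps}
        for s in cohort:
            m = s.truth_masks["ischemic"]
            for name, vol in s.maps.items():
                means[name][s.label].append(vol[m].mean())
        pvals = [ttest_ind(v["good"], v["poor"]).pvalue for v in means.values()]
        assert min(pvals) > 1e-3  # no detectable class effect


class TestSummaries:
    def test_hand_computed_summary(self):
        cohort = [generate_subject(noise_free_config(), "good", seed=i) for i in range(3)]
        for s, value in zip(cohort, (1.0, 2.0, 3.0)):
            s.maps["CBF"] = np.where(s.truth_masks["ischemic"], value, 0.0)
        summary = summarize_cohort(cohort, regions=("ischemic",))
        row = summary[(summary["map"] == "CBF")].iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(1.0)  # sample SD

    def test_constant_region_zero_sd(self, clean_subject):
        s = clean_subject
        summary = summarize_cohort([s], regions=("ischemic",))
        row = summary[summary["map"] == "Tmax"].iloc[0]
        assert row["mean"] == pytest.approx(12.0)
        assert row["sd"] == 0.0

    def test_empty_region_flagged_missing(self, clean_subject):
        import copy

        s = copy.copy(clean_subject)
        s.truth_masks = dict(s.truth_masks)
        s.truth_masks["hypoxic"] = np.zeros_like(s.truth_masks["hypoxic"])
        summary = summarize_cohort([s], regions=("hypoxic",))
        assert (summary.n_missing == 1).all()
        assert summary["mean"].isna().all()


def test_nifti_roundtrip(tmp_path, default_subject):
    meta = save_subject(default_subject, tmp_path)
    loaded = load_subject(meta["sidecar"])
    assert loaded.label == default_subject.label
    assert loaded.affected_hemisphere == default_subject.affected_hemisphere
    np.testing.assert_allclose(loaded.maps["Tmax"], default_subject.maps["Tmax"], rtol=1e-6)
    np.testing.assert_array_equal(loaded.truth_masks["ischemic"], default_subject.truth_masks["ischemic"])
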