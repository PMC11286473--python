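import warnings

import numpy as np
import pandas as pd
import pytest

from perfrad.radiomics.filters import FilterSpec
from perfrad.synthetic import (
    TABLE_CLASS_EFFECTS,
    CohortConfig,
    generate_cohort,
    generate_subject,
)

warnings.filterwarnings("ignore", message=".*constant feature.*")


def noise_free_config(**kw):
    """Deterministic phantom: zero noise, zero taper, zero between-subject SD,
    class effects well separated from the thresholds (lesion Tmax far above
    6 s) so threshold segmentation can recover the truth masks exactly."""
    effects = {
        region: {
            name: {cls: (mean, 0.0) for cls, (mean, _) in per_class.items()}
            for name, per_class in per_map.items()
        }
        for region, per_map in TABLE_CLASS_EFFECTS.items()
    }
    effects["ischemic"]["Tmax"] = {"good": (12.0, 0.0), "poor": (12.0, 0.0)}
    effects["infarct"]["Tmax"] = {"good": (14.0, 0.0), "poor": (14.0, 0.0)}
    defaults = dict(
        class_effects=effects,
        noise_sd={"CBF": 0.0, "CBV": 0.0, "MTT": 0.0, "Tmax": 0.0},
        boundary_taper_sigma=0.0,
        chi_noise_sd=0.0,
        adc_noise_sd=0.0,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def default_subject():
    return generate_subject(CohortConfig(), "poor", seed=11)


@pytest.fixture(scope="session")
def clean_subject():
    return generate_subject(noise_free_config(), "poor", seed=5)


@pytest.fixture(scope="session")
def fidelity_cohort():
    """Large cohort at the published class effects for mean-recovery checks."""
    return generate_cohort(CohortConfig(n_good=200, n_poor=200, seed=123))


@pytest.fixture(scope="session")
def planted_effect_runs():
    """The multi-seed planted-effect experiment shared by the acceptance
    checks: per seed, the best-classifier test AUC of the Ischemic_radiomics
    group, the same for a mirrored (mis-localized) control region, and —
    for the first ten seeds — the panel AUCs under permuted labels."""
    from perfrad.workflows import mirrored_control_masks, run_study

    rows = []
    for seed in range(20):
        cohort = generate_cohort(CohortConfig(seed=seed * 1000))
        ctrl = mirrored_control_masks(cohort)
        res = run_study(
            cohort=cohort, groups=("Ischemic_radiomics",),
            filters=[FilterSpec("original")], seed=seed,
            extra_radiomics_masks={"Control": ctrl},
        )
        row = {
            "seed": seed,
            "ischemic_auc": res.best_auc("Ischemic_radiomics"),
            "control_auc": res.best_auc("Control_radiomics"),
            "perm_mean_auc": np.nan,
        }
        if seed < 10:
            perm = run_study(
                cohort=cohort, groups=("Ischemic_radiomics",),
                filters=[FilterSpec("original")], seed=seed, permute_labels=True,
            )
            row["perm_mean_auc"] = float(perm.aucs("Ischemic_radiomics").mean())
        rows.append(row)
    return pd.DataFrame(rows)
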