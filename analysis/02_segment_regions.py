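"""Recompute ischemic / infarct / hypoxic masks from the generated volumes
and compare them against the generator's ground truth (Dice overlap).

The infarct mask (ADC < 620e-6 mm^2/s, recomputed from the DWI pair)
agrees exactly by construction.  The ischemic mask (Tmax > 6 s) recovers
the lesion only for subjects whose drawn regional Tmax clears the cut —
good-function subjects straddle 6 s by design.  The hypoxic mask (SvO2
grid units below 0.7) picks up extra units wherever susceptibility noise
breaks the hemispheric vein symmetry — the strict 0.7 rule has no noise
margin, which is worth seeing quantified.

Writes ``results/segmentation_agreement.csv``.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from perfrad.synthetic import CohortConfig, generate_cohort
from perfrad.workflows import segment_subject

OUT = Path(__file__).resolve().parent.parent / "results"


def dice(a, b):
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else np.nan


def main(seed: int = 0, n_subjects: int = 10):
    cohort = generate_cohort(CohortConfig(n_good=n_subjects // 2, n_poor=n_subjects - n_subjects // 2, seed=seed))
    rows = []
    for subj in cohort:
        masks = segment_subject(subj)
        for region in ("ischemic", "infarct", "hypoxic"):
            truth, rec = subj.truth_masks[region], masks[region]
            rows.append({
                "subject": subj.subject_id, "label": subj.label, "region": region,
                "truth_voxels": int(truth.sum()), "recovered_voxels": int(rec.sum()),
                "dice": dice(truth, rec),
            })
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "segmentation_agreement.csv", index=False)
    print(table.groupby("region")[["dice"]].agg(["mean", "min"]).round(3))
    print(
        "\ninfarct recovery is exact by construction (the DWI pair encodes the "
        "core); ischemic recovery tracks each subject's drawn regional Tmax "
        "relative to the 6 s cut — good-function subjects straddle it by "
        "design, exactly as thresholded clinical maps would; hypoxic "
        "over-calls because the strict 0.7 rule has no margin against "
        "susceptibility noise."
    )


if __name__ == "__main__":
    main()
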