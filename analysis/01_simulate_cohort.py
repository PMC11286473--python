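"""Generate the default 45+45 synthetic stroke cohort and check that the
realized regional perfusion statistics match the configured two-class
targets.

Writes ``results/cohort_summary.csv`` (one row per region x map x class
with realized mean/SD next to the configured targets).
"""

from pathlib import Path

import numpy as np

from perfrad.synthetic import TABLE_CLASS_EFFECTS, CohortConfig, generate_cohort, summarize_cohort

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0):
    cohort = generate_cohort(CohortConfig(seed=seed))
    summary = summarize_cohort(cohort)
    summary["target_mean"] = [
        TABLE_CLASS_EFFECTS[r.region][r["map"]][r["class"]][0] for _, r in summary.iterrows()
    ]
    summary["target_sd"] = [
        TABLE_CLASS_EFFECTS[r.region][r["map"]][r["class"]][1] for _, r in summary.iterrows()
    ]
    summary["z"] = (summary["mean"] - summary.target_mean) / (
        summary.target_sd / np.sqrt(summary.n)
    ).replace(0, np.nan)
    OUT.mkdir(exist_ok=True)
    summary.to_csv(OUT / "cohort_summary.csv", index=False)
    print(f"generated {len(cohort)} subjects (seed {seed})")
    print(summary.round(2).to_string(index=False))
    worst = summary.z.abs().max()
    print(f"\nlargest |z| of realized vs configured means: {worst:.2f} "
          f"(cohort-sized sampling noise; grows tight at larger n)")


if __name__ == "__main__":
    main()
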