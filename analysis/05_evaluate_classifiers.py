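"""Run the full comparative experiment — all 14 region/feature groups
against the six-classifier panel — on one default synthetic cohort.

Writes ``results/eval_report.csv`` (84 rows) and
``results/best_by_group.csv`` (the best classifier per group by AUC), and
prints the group ordering by best AUC.
"""

from pathlib import Path

from perfrad.radiomics.filters import FilterSpec
from perfrad.synthetic import CohortConfig, generate_cohort
from perfrad.workflows import run_study

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0):
    cohort = generate_cohort(CohortConfig(seed=seed))
    res = run_study(cohort=cohort, filters=[FilterSpec("original")], seed=seed)
    OUT.mkdir(exist_ok=True)
    res.eval_report.to_csv(OUT / "eval_report.csv", index=False)
    best = res.eval_report[res.eval_report.best].sort_values("AUC", ascending=False)
    best.to_csv(OUT / "best_by_group.csv", index=False)
    cols = ["group", "classifier", "accuracy", "sensitivity", "specificity", "PPV", "NPV", "AUC"]
    print(best[cols].round(3).to_string(index=False))
    print("\ngroups ranked by their best classifier's held-out AUC; with class "
          "effects planted in all three regions the ischemic and combined "
          "groups lead, mirroring the comparative design this emulates.")


if __name__ == "__main__":
    main()
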