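#!/usr/bin/env python
"""Re-evaluate accuracy with clamped body weight in the extreme BMI strata.

For underweight patients the weight is raised to BMI 18.5, for obese
patients lowered to BMI 30, and the WHO weight-height and Harris-Benedict
1918 equations are re-scored on the same patients (strata fixed by the
original BMI). Writes the paired accuracy table and a grouped bar chart.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from reeval.cohort import apply_inclusion_filters, read_cohort
from reeval.equations import load_coefficient_table
from reeval.validation import adjusted_weight_comparison, format_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=RESULTS / "cohort.csv")
    args = ap.parse_args()

    cohort, _ = apply_inclusion_filters(read_cohort(args.cohort))
    registry = load_coefficient_table()
    report = adjusted_weight_comparison(cohort, registry)
    report.to_csv(RESULTS / "adjusted_weight.csv", index=False)
    print(format_table(report))

    labels = [f"{r.equation}\n{r.stratum}" for r in report.itertuples()]
    x = np.arange(len(labels))
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(x - 0.2, report["pct_accurate_actual"], 0.4, label="actual weight")
    ax.bar(x + 0.2, report["pct_accurate_adjusted"], 0.4, label="adjusted weight")
    ax.set_xticks(x, labels, fontsize=8)
    ax.set_ylabel("accurate predictions (%)")
    ax.set_ylim(0, 100)
    ax.legend()
    fig.tight_layout()
    fig.savefig(RESULTS / "adjusted_weight.png", dpi=150)

    improved = report["pct_accurate_adjusted"] > report["pct_accurate_actual"]
    if not improved.any():
        print("\nClamping weight did not improve accuracy in any stratum,")
        print("matching the conclusion that fixed-BMI weight adjustment fails to help.")
    else:
        rows = report[improved]
        print("\nIn this synthetic run clamping improved accuracy for "
              + ", ".join(f"{r.equation}/{r.stratum}" for r in rows.itertuples()) + ".")
        print("The synthetic truth model is itself weight-linear, so shifting weight")
        print("toward the band can offset another equation's systematic bias — a")
        print("behaviour the real cohort, with its physiological REE, did not show.")


if __name__ == "__main__":
    main()
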