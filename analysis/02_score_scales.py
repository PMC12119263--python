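#!/usr/bin/env python
"""Score CESD-10, GAD-7 and SSRS and summarise the screening outcomes.

Reads the cohort written by 01_simulate_cohort.py, appends totals and
binary screening outcomes, and reports the depression/anxiety screening
prevalences, their overlap, and the rank correlation of the two scale
scores.
"""

from pathlib import Path

import pandas as pd

from qcascreen import scales
from qcascreen.regression import spearman_scores

OUT = Path("results/analysis")


def main() -> None:
    raw = pd.read_csv(OUT / "cohort.csv")
    sc = scales.score_cohort(raw)
    sc.to_csv(OUT / "scored.csv", index=False)

    n = len(sc)
    n_dep = int(sc.depression_positive.sum())
    n_anx = int(sc.anxiety_positive.sum())
    n_both = int((sc.depression_positive & sc.anxiety_positive).sum())
    rho, p = spearman_scores(sc.cesd_total, sc.gad_total)

    summary = pd.DataFrame(
        {
            "quantity": [
                "n", "depression_positive", "depression_prevalence_pct",
                "anxiety_positive", "anxiety_prevalence_pct",
                "comorbid", "comorbid_share_of_depressed_pct",
                "spearman_cesd_gad", "spearman_p",
            ],
            "value": [
                n, n_dep, round(100 * n_dep / n, 1),
                n_anx, round(100 * n_anx / n, 1),
                n_both, round(100 * n_both / n_dep, 1),
                round(rho, 3), p,
            ],
        }
    )
    summary.to_csv(OUT / "screening_summary.csv", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
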