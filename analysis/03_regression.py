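#!/usr/bin/env python
"""Backward-eliminated logistic regression for both screening outcomes.

Fits the full covariate set for depression- and anxiety-positivity,
removes predictors by likelihood-ratio tests (threshold 0.10), and writes
forest-plot-ready tables (level, OR, CI, p, reference flag).
"""

from pathlib import Path

import pandas as pd

from qcascreen import pipeline
from qcascreen.regression import backward_eliminate

OUT = Path("results/analysis")


def main() -> None:
    sc = pd.read_csv(OUT / "scored.csv")
    for outcome, ycol in (
        ("non_depression", "depression_positive"),
        ("non_anxiety", "anxiety_positive"),
    ):
        reg = backward_eliminate(
            sc, ycol, pipeline.REGRESSION_PREDICTORS, pipeline.REGRESSION_CATEGORICAL
        )
        reg.table.to_csv(OUT / f"regression_{outcome}.csv", index=False)
        kept = reg.table.loc[~reg.table.reference]
        print(f"\n{ycol}: eliminated {reg.eliminated or '(none)'}")
        print(
            kept[["variable", "level", "odds_ratio", "ci_low", "ci_high", "p_value"]]
            .round(3).to_string(index=False)
        )


if __name__ == "__main__":
    main()
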