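#!/usr/bin/env python
"""Necessity analysis, truth tables and fsQCA solutions for both outcomes.

Uses the survey-scale thresholds (frequency 10; consistency 0.85 for the
depression outcome, 0.80 for anxiety) and the default directional
expectations; writes necessity tables, configuration tables and plain-text
configuration charts.
"""

from pathlib import Path

import pandas as pd

from qcascreen import pipeline
from qcascreen.calibration import calibrate_dataset
from qcascreen.qca import configuration_chart, run_fsqca

OUT = Path("results/analysis")


def main() -> None:
    sc = pd.read_csv(OUT / "scored.csv")
    specs = pipeline.default_calibration_specs(sc)
    for outcome in ("non_depression", "non_anxiety"):
        thr = pipeline.DEFAULT_CONS_THRESHOLDS[outcome]
        fds = calibrate_dataset(sc, specs, outcome, case_id_col="case_id")
        rep = run_fsqca(fds, freq_threshold=10, cons_threshold=thr,
                        expectations=pipeline.DEFAULT_EXPECTATIONS)
        pipeline._necessity_frame(rep).to_csv(OUT / f"necessity_{outcome}.csv", index=False)
        pipeline._configuration_frame(rep).to_csv(OUT / f"configurations_{outcome}.csv", index=False)
        chart = configuration_chart(rep.intermediate, rep.condition_names)
        (OUT / f"chart_{outcome}.txt").write_text(chart + "\n", encoding="utf-8")

        max_nec = max(r.consistency for r in rep.necessity)
        print(f"\n=== {outcome} (consistency threshold {thr}) ===")
        print(f"necessity: max consistency {max_nec:.3f} "
              f"({'no condition necessary' if max_nec <= 0.9 else 'necessary condition found'})")
        print(chart)


if __name__ == "__main__":
    main()
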