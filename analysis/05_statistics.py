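#!/usr/bin/env python
"""Statistical comparison of dose-function metrics and reader agreement.

Friedman test across the four imaging methods per (metric, threshold), then
post-hoc Wilcoxon signed-rank tests of each novel method against the HU
reference at the Bonferroni-adjusted alpha (0.05/3 -> 0.016).  Also
simulates radiologist defect calls per arm and summarizes the agreement
with the HU arm as sensitivity / precision / specificity / accuracy, with
and without attention to lobe location.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import COHORT_SEED, RESULTS

from vent4d.phantom import simulate_reader
from vent4d.stats import binary_agreement, friedman_test, posthoc_wilcoxon


def dose_function_stats(df):
    rows = []
    for (metric, level), sub in df.groupby(["metric", "level"]):
        wide = sub.pivot(index="patient", columns="method", values="value").dropna()
        fr = friedman_test(wide.to_numpy(), label=f"{metric}_ge{level}_friedman")
        rows.append(fr)
        novel = [c for c in ("IJF", "MCVC", "Perf") if c in wide.columns]
        rows += posthoc_wilcoxon(
            wide["HU"].to_numpy(),
            {f"{metric}_ge{level}_{m}_vs_HU": wide[m].to_numpy() for m in novel},
            m=len(novel),
        )
    return pd.DataFrame(
        [{"label": r.label, "statistic": r.statistic, "p_value": r.p_value,
          "adjusted_alpha": r.adjusted_alpha, "significant": r.significant}
         for r in rows]
    )


def reader_agreement(truth_df):
    truths = [
        (row.patient, bool(row.has_defect), row.defect_lobe)
        for row in truth_df.itertuples()
    ]
    reference = simulate_reader(truths, 0.85, 0.85, 0.1,
                                seed=COHORT_SEED + 7, method="HU")
    rows = []
    for k, method in enumerate(("IJF", "MCVC", "Perf")):
        arm = simulate_reader(truths, 0.85, 0.85, 0.1,
                              seed=COHORT_SEED + 8 + k, method=method)
        for use_loc in (False, True):
            s = binary_agreement(reference, arm, use_location=use_loc)
            rows.append({
                "method": method, "with_location": use_loc,
                "sensitivity": s.sensitivity, "precision": s.precision,
                "specificity": s.specificity, "accuracy": s.accuracy,
            })
    return pd.DataFrame(rows)


def main():
    df = pd.read_csv(RESULTS / "dose_function.csv")
    stats = dose_function_stats(df)
    stats.to_csv(RESULTS / "stats.csv", index=False)
    print(stats.round(4).to_string(index=False))

    truth = pd.read_csv(RESULTS / "cohort_truth.csv")
    agree = reader_agreement(truth)
    agree.to_csv(RESULTS / "reader_agreement.csv", index=False)
    print("\nreader agreement vs the HU arm:")
    print(agree.round(3).to_string(index=False))
    print(f"\nwrote {RESULTS / 'stats.csv'} and {RESULTS / 'reader_agreement.csv'}")


if __name__ == "__main__":
    main()
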