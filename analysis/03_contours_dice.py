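#!/usr/bin/env python
"""Functional contours and Dice overlap of each novel method against HU.

Loads the function images written by 02_function_images.py, converts them
to percentile images, thresholds at >=25/50/75%, and tabulates the Dice
similarity of each novel method's contour against the density-change (HU)
reference — the per-method, per-threshold comparison the study design
centers on.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import N_PATIENTS, RESULTS

import vent4d.io as vio
from vent4d.contours import dice, threshold_contour, to_percentile

KINDS = {"HU": "specific-volume-change", "IJF": "jacobian",
         "MCVC": "jacobian", "Perf": "mass-change-magnitude"}


def main():
    rows = []
    for i in range(N_PATIENTS):
        pid = f"P{i:03d}"
        pdir = RESULTS / "images" / pid
        mask = vio.load_mask(pdir / "lung_mask.nii.gz")
        pct = {
            name: to_percentile(vio.load_function(pdir / f"func_{name}.nii.gz", kind), mask)
            for name, kind in KINDS.items()
        }
        for name in ("IJF", "MCVC", "Perf"):
            for level in (25, 50, 75):
                d = dice(
                    threshold_contour(pct[name], level, name),
                    threshold_contour(pct["HU"], level, "HU"),
                )
                rows.append({"patient": pid, "method": name, "level": level, "dsc": d})
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "dice.csv", index=False)
    summary = df.groupby(["method", "level"]).dsc.mean().unstack().round(3)
    print("mean DSC vs HU reference:")
    print(summary)
    print(f"wrote {RESULTS / 'dice.csv'}")


if __name__ == "__main__":
    main()
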