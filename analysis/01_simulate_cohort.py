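#!/usr/bin/env python
"""Generate the synthetic patient cohort and summarize its ground truth.

Each patient is an inhale/exhale phantom pair with a known analytic
Jacobian; the script records per-patient truth statistics (mean expansion,
defect presence, lung volume) to results/cohort_truth.csv.  The phantoms
themselves are regenerated deterministically by seed in the later scripts,
so no bulky volumes need to be stored.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import COHORT_SEED, N_PATIENTS, NOISE_SD_HU, RESULTS, SHAPE

from vent4d.pipeline import RunConfig, _patient_phantom


def main():
    cfg = RunConfig(n_patients=N_PATIENTS, shape=SHAPE, seed=COHORT_SEED,
                    noise_sd_hu=NOISE_SD_HU)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for i in range(N_PATIENTS):
        ph, has_defect, lobe, _ = _patient_phantom(cfg, i, rng)
        m = ph.mask.values
        rows.append({
            "patient": f"P{i:03d}",
            "lung_voxels": int(ph.mask.n_voxels),
            "lung_volume_cm3": ph.mask.volume_mm3 / 1000.0,
            "mean_jacobian": float(ph.truth.jacobian[m].mean()),
            "has_defect": has_defect,
            "defect_lobe": lobe,
        })
    RESULTS.mkdir(exist_ok=True)
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "cohort_truth.csv", index=False)
    print(f"cohort of {N_PATIENTS} phantoms "
          f"(mean lung volume {df.lung_volume_cm3.mean():.0f} cm^3, "
          f"mean J {df.mean_jacobian.mean():.3f}, "
          f"{int(df.has_defect.sum())} with defects)")
    print(f"wrote {RESULTS / 'cohort_truth.csv'}")


if __name__ == "__main__":
    main()
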