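"""Shared cohort definition for the analysis scripts.

A small synthetic cohort stands in for the clinical 4DCT series: each
patient is a 32^3 breathing phantom (2 mm voxels) with a random mild
anisotropic expansion, half of them carrying a ventilation defect.
"""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"
COHORT_SEED = 2026
# 8 patients is the smallest cohort for which the exact two-sided Wilcoxon
# can fall below the Bonferroni-adjusted alpha (2/2^8 = 0.008 < 0.016)
N_PATIENTS = 8
SHAPE = (32, 32, 32)
NOISE_SD_HU = 20.0
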