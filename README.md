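# vent4d

4DCT-based lung ventilation/perfusion imaging and functional-avoidance
analysis on synthetic breathing phantoms with analytic ground truth.

Functional avoidance radiotherapy spares the well-functioning lung by
steering dose away from it, which requires a voxelwise map of lung
function. Respiration-correlated CT (4DCT) can provide one without extra
imaging: the exhale phase, the inhale phase, and the deformable
registration between them already encode regional volume change. This
package implements the classical density-change ventilation map and three
uncertainty-controlled alternatives, plus the full comparison chain used
to ask whether the choice of method changes the clinical picture.

**The four function images** (exhale grid, lung mask only):

* `vent_hu` — density change: SV(x) = 1000 (H_in − H_ex) / (H_ex (1000 + H_in)),
  the specific air-volume change under the two-material (air/water) model;
* `vent_ijf` — integrated Jacobian: subregional deformed volumes measured
  by hit-or-miss Monte Carlo over mapped tetrahedra (sample size set by a
  tolerance τ), then a voxelwise Jacobian J(x) recovered by constrained
  linear least squares whose total matches the inhale lung volume;
* `vent_mcvc` — mass conservation: subregional Jacobians as density
  ratios Ĵ_r = mean ρ_ex / mean ρ_in(x+u), recovered voxelwise with J ≥ ε;
* `perf_image` — perfusion surrogate: voxelwise magnitude of the
  breathing-induced mass change |J ρ_in(x+u) − ρ_ex|, reconstructed with a
  non-negativity bound.

Downstream, images become percentile maps (rank over the lung), ≥25/50/75 %
functional contours, Dice overlaps against the HU reference, dose-function
metrics (fMLD = mean dose in a contour, fV20 = % of contour ≥ 20 Gy; 24
records per patient), simulated-reader confusion summaries, and
Friedman + post-hoc Wilcoxon tests at the Bonferroni-adjusted alpha
0.05/3 → 0.016. A synthetic phantom generator supplies mass-consistent
inhale/exhale pairs with closed-form Jacobians, implanted ventilation
defects and perfusion anomalies, conformal dose, and reader calls — see
`docs/methods.md`.

## Worked example

```python
import numpy as np
import vent4d as v
from vent4d.core import build_partition

ph = v.make_phantom(shape=(48, 48, 48), noise_sd_hu=0.0, seed=7)
part = build_partition(ph.mask)           # cubic subregions, window 8, stride 4
img = v.vent_mcvc(ph.exhale, ph.inhale, ph.field, ph.mask, part)

m = ph.mask.values
J = ph.truth.jacobian
rmse = np.sqrt(np.mean((img.values[m] - J[m]) ** 2)) / J[m].mean()
print(f"true J = {J[m].mean():.4f}, recovered {np.nanmean(img.values[m]):.4f}, "
      f"RMSE {100 * rmse:.3f}%")
```

prints

```
true J = 1.1576, recovered 1.1576, RMSE 0.018%
```

i.e. on a noise-free 5 %-per-axis expansion (J = 1.05³ ≈ 1.158) the
mass-conserving reconstruction recovers the analytic Jacobian to a small
fraction of a percent.

The full study is scripted under `analysis/`:

```bash
python analysis/01_simulate_cohort.py     # 8 phantoms, truth summary
python analysis/02_function_images.py     # 4 images/patient + accuracy table
python analysis/03_contours_dice.py       # DSC of novel methods vs HU
python analysis/04_dose_function.py       # 24 dose-function records/patient
python analysis/05_statistics.py          # Friedman, Wilcoxon, reader agreement
```

Tables land in `results/`. The same pipeline is available in one call as
`vent4d run --seed 0 --out results/run` (see `vent4d --help` for the
`phantom`, `vent`, `contours`, `dosefunc`, and `stats` subcommands).

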