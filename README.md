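# ismpop

**In situ microscopy (ISM) cell-population monitoring for bioreactor
cultures** — synthetic micrograph and kinetics generation, a reference
morphological six-class cell detector, probe-volume density calibration and
viability accounting, with the evaluation statistics used to validate such
monitoring systems.

## The problem

An in situ microscope mounted on a stirred-tank bioreactor images cells
drifting past a window under flash illumination. Only cells inside a thin
optical *probe volume* appear sharp; counting them per frame gives an
online, non-invasive estimate of culture density. Classifying each sharp
cell by its morphology — the established visual criteria for viable,
apoptotic and necrotic mammalian cells — turns the same image stream into a
per-class density and viability monitor for antibody-producing hybridoma
cultures.

`ismpop` implements that monitoring computation end to end as a reusable,
fully tested pipeline, replacing the two pieces that cannot be shipped on a
desk — the bioreactor and the trained CNN detector — with first-class
synthetic counterparts:

* **`ismpop.synthetic`** — a six-pool kinetic model of a hybridoma batch →
  continuous culture (Monod growth on substrate and dissolved oxygen,
  reversible viable ↔ "viable with bulges" transition under feast/famine
  conditions, stress-driven apoptosis/necrosis, dilution/washout), Poisson
  probe-volume count sampling, trypan-blue-like offline reference samples
  with the assay's known error structure, and an 8-bit micrograph renderer
  with per-class morphology templates, defocus blur and ground-truth
  annotations.
* **`ismpop.detection`** — a classical (non-learned) detector: contrast
  segmentation, Laplacian focus filtering (which *defines* the effective
  probe depth), interpretable shape/texture features and ordered
  classification rules for the six classes; darknet/YOLO-format annotation
  I/O for interop with external detectors.
* **`ismpop.accounting`** — the core monitoring math: `X(t) = α·y(t)`
  density calibration (α in image/mL is the inverse probe volume),
  viable/dead pooling, viability, moving-average smoothing and event-wise
  relative-change tables.
* **`ismpop.validation`** — MAPE against offline references, regression
  through the origin for α, greedy-matched all-point-interpolated AP/mAP,
  confusion analysis and coefficient of variation.
* **`ismpop.cli`** — `ismpop simulate | render | detect | monitor |
  calibrate | evaluate`, driven by one YAML config with a global seed.

The six morphological classes (ids as in the annotation format):

| id | class | morphology |
|----|-------|------------|
| 1 | viable | pseudo-circular, homogeneous texture |
| 2 | apoptotic | irregular, shrunken, inhomogeneous, vesicles |
| 3 | necrotic | swollen, almost perfectly round, inhomogeneous |
| 4 | viable with bulges | distinct surface bulges (feast/famine morphotype) |
| 5 | necrotic late stage | blurred discontinuity of the cell border |
| 6 | pair | two attached viable cells (mitotic twins) |

Viable density pools classes 1 + 4 + 6 (a pair counts once), dead density
pools 2 + 3 + 5, and viability is the viable share of the total in percent.

## Worked example

Simulate the 145-h reference recipe (75.5 h batch, then continuous at
D = 0.0125/h, with offgas clogging, a medium addition, substrate limitation
and an oxygen shutdown), sample ISM counts at 1000 images per point,
convert to densities and compare with offline reference samples:

```python
import numpy as np
from ismpop import *
from ismpop.config import default_config

cfg = default_config(seed=1)
traj = simulate_bioprocess(cfg.kinetics, cfg.events, cfg.init, cfg.t_end, cfg.dt)
times = np.arange(0.25, cfg.t_end, 0.25)
counts = sample_ism_counts(traj, cfg.alpha, n_images_per_point=1000,
                           seed=cfg.seed, sample_times=times)
dens = DensitySeries.from_counts(counts, cfg.alpha).smoothed(cfg.smoothing_window)

i = int(np.argmin(np.abs(dens.time - 48.25)))
print(f"t = {dens.time[i]:.2f} h")
print(f"viable total = {dens.viable_total[i]:.3e} cell/mL")
print(f"dead total   = {dens.dead_total[i]:.3e} cell/mL")
print(f"viability    = {dens.viability[i]:.1f} %")

ref = generate_offline_reference(traj, np.arange(4.0, 145.0, 8.0), seed=2)
print(f"MAPE density   = {mape(ref, dens, 'density'):.2f} %")
print(f"MAPE viability = {mape(ref, dens, 'viability'):.2f} %")

ys = [counts.mean_counts[np.argmin(np.abs(times - s.time))].sum() for s in ref]
model = fit_alpha(list(zip(ys, [s.density for s in ref])))
print(f"alpha fit      = {model.alpha:.3e} image/mL (r = {model.r:.2f})")
```

prints

```
t = 48.25 h
viable total = 1.037e+06 cell/mL
dead total   = 1.786e+05 cell/mL
viability    = 85.3 %
MAPE density   = 17.62 %
MAPE viability = 5.40 %
alpha fit      = 3.007e+06 image/mL (r = 0.81)
```

The density MAPE is dominated by the offline assay's own ~20% counting
error while the viability MAPE stays small — exactly the asymmetry the
dye-exclusion reference is known for — and the calibration recovers the
true probe-volume coefficient (3.2 × 10⁶ image/mL) to within the reference
noise.

The same steps are available from the shell:

```bash
ismpop simulate --seed 1 --out out/          # trajectory.csv with phase flags
ismpop render   --seed 1 --time 30 --n-frames 10 --out frames/
ismpop detect   --frames frames/ --out dets/
ismpop monitor  --counts counts.csv --out mon/   # density.csv + event_table.csv
```

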