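# Methods

This note documents the models, numerical choices and limitations behind
`ismpop`. Everything stated here is computed by the package's tests or by
`scripts/acceptance.py`; nothing is an external empirical claim.

## Monitoring model

The quantity the pipeline estimates is the per-class culture density
X_c(t) (cell/mL) from the mean number of sharp, in-focus class-c cells per
image, y_c(t):

    X_c(t) = α · y_c(t)

α (image/mL) is the calibration coefficient, interpreted as the inverse of
the optical probe volume: each frame effectively samples 1/α mL. The
reference value used throughout is α = 3.2 × 10⁶ image/mL, i.e. a probe
volume of ≈ 0.31 nL per frame. `fit_alpha` estimates α by least squares
through the origin (the model has no intercept by construction) and
reports both the Pearson correlation r of (y, X) and r², because a single
"correlation of the fit" number is ambiguous between the two.

Pooling rules: viable density = class 1 + class 4 + class 6; dead density
= class 2 + class 3 + class 5; viability = 100 · viable/total. A pair
(class 6) contributes its density **once** — it is a detection unit, not
two counted cells; the per-class event tables treat it as its own column
and doubling it would break the viability arithmetic of the reference
data. The alternative is exposed as nothing more than doubling the pair
column before pooling, deliberately not a hidden flag inside
`pool_and_viability`. With zero total density the viability is NaN, never
0 or 100.

Event accounting reports, for each operator-logged process event and each
class, the integer relative change round((end−start)/start·100), rounded
half **away from zero** — the only rule consistent with all 54 recorded
integer percentages of the reference run (e.g. −77.5 → −78). Series
endpoints are read at the nearest grid point by default; linear
interpolation is available. Smoothing is a centred moving average (default
window 5 points, odd windows only) with shrinking edge windows; periodic
padding is available where exact mean preservation matters.

Process arithmetic for the continuous phase: D = harvest flow / working
volume = (1.5 L/day)/(24 h/day · 5 L) = 0.0125 h⁻¹; mean residence time
1/D = 3.33 days. D < µmax (0.04 h⁻¹) is what keeps the continuous culture
from washing out; the simulator reproduces washout when D > µmax.

## Culture simulator

`simulate_bioprocess` integrates eight states — six class densities,
substrate S (g/L), dissolved oxygen O (% sat) — with fixed-step RK4
(default dt = 0.05 h). The system is non-stiff by construction (all rates
≲ 1 h⁻¹), so a fixed step gives bit-reproducible trajectories.

* **Growth**: Monod in both resources, µ = µmax·S/(Ks+S)·O/(Ko+O), acting
  on viable singles and bulged viable cells. µmax = 0.04 h⁻¹ is the
  operating value of the emulated process; Ks, Ko are plumbing constants.
  A half-saturation of exactly 0 means "saturated whenever the resource is
  present", which gives closed-form exponential growth for testing
  (doubling time ln 2/0.04 ≈ 17.3 h).
* **Pairs**: a fraction k_pair of division events passes through a visible
  pair state: the mother leaves the singles pool, one pair unit appears,
  and splitting (k_split) returns two singles. The countable-cell influx
  is therefore (1−k_pair)·µ·(v+b) + k_split·p, and with lysis and dilution
  off the summed density obeys d(total)/dt = influx exactly — verified
  numerically to 1e-6 relative.
* **Feast/famine bulges**: the signal is |dS/dt|/S above a threshold
  (abrupt substrate change, e.g. a medium addition) **or** S below a
  famine limit. The viable ↔ bulged exchange runs both ways at baseline
  rates (giving a standing bulged subpopulation, as observed in such
  cultures); the signal raises the on-rate and its clearing raises the
  off-rate, producing the documented rapid shift into the bulged state and
  return to the pre-event share afterwards.
* **Death routes**: apoptosis and necrosis drain both viable pools at
  base + stress·weight rates. Stress weights accumulate from events
  (offgas blocking, oxygen depletion, substrate limitation) and from the
  state itself (hypoxia below o_lim, famine below s_lim); substrate stress
  preferentially drives necrosis and oxygen stress apoptosis, matching the
  qualitative event responses of the reference run. Necrotic cells mature
  to late-stage necrosis (k_late); late-stage cells may lyse out of the
  observable population (k_lysis) — whether lysed cells vanish is not
  observable from the data, so it is an explicit knob defaulting to a
  small positive rate.
* **Events**: medium additions spread their substrate over the event
  window; oxygen depletion drives the DO setpoint to zero (first-order
  relaxation, o2_rate); feed_start applies dilution D to every state and
  feeds substrate at D·(S_feed − S). If the schedule contains no
  feed_start event but D > 0, the whole run is a chemostat — that is how
  the washout property is exercised.
* **Failure mode**: any step driving a state meaningfully negative (beyond
  1e-9 of the state scale) raises `IntegrationError`; sub-roundoff dust is
  snapped to exactly zero. Silent clipping of genuinely negative states is
  deliberately not performed.

The default initial state (4 × 10⁵ cell/mL total at 85% viability, with
the class composition in the proportions logged early in the reference
run) resolves a documented inconsistency in the source description between
the measured seeding density (6 × 10⁵) and the stated initial density
(≈ 4 × 10⁵) in favour of the latter. Rate-constant defaults were chosen
once so the default 145-h recipe reproduces the reference run's magnitudes
(total density growing from 4 × 10⁵ to ≈ 1.3 × 10⁶ cell/mL, viability
declining after the oxygen shutdown, continuous-phase decline without
washout); they are not fitted quantities.

## Probe-volume sampling and offline reference

Per image, the number of class-c cells is Poisson with mean X_c/α,
independent across images and classes; each counted cell's reported class
is re-drawn from a row-stochastic 6×6 confusion matrix (identity by
default; a symmetric 1↔4 swap emulates the characteristic viable/bulged
ambiguity of morphological classifiers). Experimental points aggregate
n_images (default 1000, the aggregation floor used when points are built
from raw frames). At the default operating range this gives 0.13–0.54
cells/image, so a 1000-image point carries a 4–9% relative Poisson error —
which is why the end-to-end density recovery lands near 4.5% MAPE.

Offline (dye-exclusion-like) reference samples add: Gaussian viability
noise of 5 percentage points, inflated to a configured 18.8% coefficient
of variation once true viability drops below 28% (ambiguous staining of
dying cells, few counted cells); and multiplicative lognormal density
noise with 20% relative sd (mean-preserving parameterization). Outputs are
clipped to [0, 100]% and ≥ 0.

## Renderer and reference classifier

Frames are 1392 × 1040 px, 8-bit, flat background (grey 128, sd 3) at
0.158 µm/px (a 0.22 × 0.16 mm² object field). Each cell is a radial
boundary profile r(θ) per class: near-circular and homogeneous (1),
shrunken with strong low-order irregularity plus roughness and bright
vesicles (2), swollen and almost perfectly round with strong cytoplasmic
speckle (3), five raised-cosine surface lobes (4), round/speckled with one
border arc whose rim contrast and edge sharpness fade to background (5),
and two overlapping discs (6). Texture is tapered to zero at the membrane
so speckle never erodes the segmented contour. Cells beyond half the depth
of field (6 µm) are composited with premultiplied-alpha Gaussian blur
growing with defocus and are excluded from the ground-truth annotations;
cells in front of the focal plane are brightened, behind it darkened
(lensing asymmetry). Rendering is deterministic: one seeded generator per
cell texture plus one for the background.

The reference detector thresholds |I − background| at a multiple of the
robust (MAD) noise, opens/closes/fills, and filters components by area;
border-touching components showing less than half the nominal cell area
are dropped, mirroring the labelling convention for peripheral cells. The
focus score is Var(Laplacian of the σ=1 smoothed frame) over the region,
normalized by the region's intensity variance plus a noise floor (25
grey²) so flat low-contrast blobs cannot pass on pixel noise; the
threshold (0.085) was calibrated once against rendered in-focus vs
defocused cells and frozen. The effective probe depth is a monotone
function of this threshold — the optical depth of field is defined by the
algorithm, not the lens.

Features and ordered rules: distance-transform peak count ≥ 2 → pair;
smoothed min/median radial edge contrast < 0.25 → late necrotic; ≥ 4
convexity defects deeper than 0.10·r_eq → viable with bulges; interior
coefficient of variation ≥ 0.065 and circularity (4πA/P², Crofton
perimeter) ≥ 0.92 → necrotic; inhomogeneous but irregular → apoptotic;
otherwise viable. All thresholds live in `ClassifierThresholds`, were
calibrated once against the renderer's templates, and are frozen in the
default configuration. On clean single-cell frames this classifier is
essentially perfect; that validates the pipeline's plumbing, **not**
real-micrograph performance — the renderer does not model halos, debris,
overlapping cells, illumination gradients or the continuum of intermediate
morphologies, which is precisely why learned detectors earn their keep on
real data.

Structural fidelity is tested instead of absolute numbers: shrinking the
rendered bulge amplitude toward zero collapses class-4 recall into class-1
predictions (the documented viable ↔ bulged confusability), and pooling
classes 1 + 4 at evaluation time recovers a perfect mAP when the only
errors are 1↔4 swaps.

## Detection evaluation

AP uses greedy one-to-one matching by descending confidence at IoU ≥ 0.5
(configurable) and the all-point interpolated area under the
precision–recall curve; mAP averages the classes present in the ground
truth, and a class with no ground-truth instance is reported as absent,
never as zero. The implementation is cross-checked for exact agreement
against an independent brute-force oracle that re-derives the PR staircase
from scratch for every confidence prefix (1000 random instances with up to
six boxes per side). The matching/interpolation protocol of external
evaluations is rarely stated, so both knobs are explicit configuration.

## Problem sizes

Defaults used by the tests and the acceptance script: 145-h trajectory at
dt = 0.05 h; 579 sampling points at 0.25-h cadence with 1000 images each;
100 rendered frames per class for classifier accuracy; 500 replicates for
the offline CV; 1000 random instances for the AP oracle; 400 h at
D = 0.05 h⁻¹ for washout. These sizes make the whole suite run in a few
minutes on one CPU while keeping Monte-Carlo error well inside the
asserted tolerances.

## Known limitations

* The renderer's morphology templates are idealized; per-class accuracy
  measured on them is an upper bound with no bearing on real micrographs.
* The kinetic model is a phenomenological six-pool ODE; its rate constants
  (other than µmax and D) are plausibility choices, not measurements, and
  event responses match the reference run qualitatively, not row by row.
* Overlapping cells are not specially handled: a merged blob with two
  distance-transform peaks is called a pair, conflating mitotic twins with
  chance overlaps. The labelling convention the pipeline mirrors simply
  omitted overlaps.
* The confusion overlay redraws classes independently per counted cell; it
  does not model spatially correlated errors or detector misses.
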