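# Methods

## Scope and model

`vitiphen` models grapevine phenology as a per-interval 4-way classification
problem on season-relative time. A site-season is 365 days starting at the
zone's local season start; 26 biweekly intervals tile days 1–364. The label of
an interval is the developmental stage at its midpoint day, derived from
accumulated thermal time: GDD(d) = Σ_{d'≤d} max(0, T(d') − T_base) with
T_base = 10 °C and onset thresholds budburst 50, flowering 400, veraison
1000, harvest 1400 GDD. Stages are contiguous — a stage persists from its
onset until the next stage's onset — because per-interval labels need a total
labeling; the published upper band edges (100/600/1200/1800 GDD) are retained
as metadata only. Intervals before budburst carry an internal `pre_season`
label that is excluded from classifier training and scoring, since the
classifier's output space is the four agronomic stages.

Stage onsets are reported as days. Ground truth resolves onsets to the exact
GDD-crossing day; predictions resolve them to the midpoint of the first
interval classified with the stage. This quantization alone contributes up to
±7 days of onset error even for a perfect interval classifier, which is why
onset-error targets are stated in units of the 14-day interval.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical envelope of satellite pixel time
series over three agroecological zones (Mediterranean 40%, subtropical 30%,
temperate 30% of sites, with zone-typical coordinates):

- **Weather.** Temperature is an annual sinusoid (zone mean and amplitude,
  hemisphere-phased, Gaussian noise sd 1.5 °C). Rainfall is an intermittent
  gamma process with a seasonal wet-day probability, rescaled so each season's
  total falls in the zone's range (Mediterranean 600–800, subtropical
  400–550, temperate 700–900 mm/yr; the garbled temperate figure "7–900" is
  read as 700–900). Relative humidity is 55% + 25% on rain days + noise,
  clipped to [20, 100] — a placeholder adequate for threshold rules, not a
  humidity model.
- **Vegetation.** NDVI follows a double-logistic canopy curve keyed to the
  thermal-time onsets (green-up after budburst, plateau through veraison,
  senescence after harvest), base 0.15 / peak 0.83, rise constant 13 days and
  fall constant 16 days, plus truncated (±2 sd) Gaussian noise of sd 0.02,
  clipped to [0.10, 0.85]. These constants were set once so that (a) the
  population NDVI mean lands near 0.45 and EVI (an affine companion mapped
  onto [0.08, 0.75]) near 0.38, and (b) the maximum clean biweekly |ΔNDVI|
  stays ≤ 0.28, strictly below the 0.3 contamination threshold.
- **Contamination.** Cloud spikes depress NDVI by an amount drawn from
  N(0.47, 0.12) truncated to [0.31, 0.75], imposed against the previous
  step's clean value so the realized inter-step decrease matches the drawn
  magnitude; spikes target vegetated steps (clean NDVI > 0.45) because the
  low off-season baseline cannot absorb such a drop within the −0.2 sensor
  floor. A 1.78% fraction of series is heavily contaminated (9–13 spiked
  steps) to exercise the series-drop rule. Missing runs hit 28.47% of series,
  with run-length classes {1, 2, 3, 4–6, >6} drawn in proportions
  0.734/0.171/0.058/0.027/0.010 (the published census of gap counts), giving
  ~3.2% missing timesteps overall.

What passing tests on this data do **not** show: robustness to sensor
saturation, mixed pixels, multi-year carry-over, cultivar differences,
irrigation, or any real geography — the generator has none of these. The
classifier's high synthetic accuracy mostly reflects that stage is a smooth
function of elapsed season time plus weather, which the causal pseudo-image
(whose zeroed tail also encodes the current interval index) captures well.

## Preprocessing choices

- Spike flagging compares each observed step against the previous *observed*
  value (strict inequality at 0.3); both rises and drops are flagged, so a
  single depressed step yields two censored steps (the drop and the
  recovery). Flagged steps censor NDVI and EVI; rainfall is a ground/
  reanalysis variable and is untouched.
- A series is dropped when flagged plus originally-missing steps exceed 30%
  of 26 (strict), i.e. at 9 bad steps, not 7.
- Imputation dispatch: L = 1 linear; L ∈ {2, 3} cubic spline (not-a-knot,
  exact on cubic polynomials); L > 3 LOESS with tricube weights over observed
  points within ±6 intervals (window widened until ≥4 points). The local
  polynomial is **degree 2**: with the nearest observations 1–3 steps away, a
  local line leaves a curvature bias (~0.04 RMSE on seasonal trajectories)
  that dominates the 0.02 observation noise, while the quadratic term removes
  it. Edge gaps with a single anchor use nearest-value extension when short,
  LOESS otherwise.
- Min–max normalization bounds are fitted on training folds only and reused
  on held-out folds (out-of-range values clipped); fitting on the full
  dataset leaks test information and is deliberately not the default.

## The augmented dream optimizer

Minimization over a box, mixed scales (learning rate searched in log10
units). Defaults: 5 static round-robin groups, exploration for
Td = ⌊0.9·Tmax⌋ iterations then exploitation, forgetting/supplementing vs
dream-sharing switch u = 0.9, PSO blend α = 0.6, γ1 = γ2 = 2.0, inertia
w = 0.7. Numerical conventions worth stating:

- The exploration perturbation is x ← x_best,q + U(X_l, X_u)·½(cos(π(t +
  Tmax − Td)/Tmax) + 1), so its amplitude decays smoothly to zero exactly at
  t = Td; the exploitation counterpart uses ½(cos(πt/Tmax) + 1), vanishing at
  t = Tmax.
- `randi(lo, hi)` is inclusive; lo > hi resolves to hi; forget counts are
  clamped to [1, Dim]. In exploitation every agent forgets the same number of
  dimensions per iteration.
- The PSO velocity uses uniform random multipliers r1, r2 (standard PSO); a
  `paper_pso` switch removes them for the deterministic-coefficient variant.
- Dream-sharing copies from the live population array, so donors with a
  smaller index contribute their already-updated coordinate; self-copying is
  disallowed.
- Bounds repair: ≤15 dimensions resample the violating coordinate uniformly;
  >15 dimensions copy it from a random other agent.
- Non-finite objective values are recorded as +∞ and the run continues; there
  is no explicit rollback of worsened agents — the next iteration's memory
  reset restores the remembered best anyway.

On the 5-D sphere over [−5, 5]^5 with N = 30 and Tmax = 300, 20/20 seeded
runs reach a best below 1e−2 (median ≈ 5e−8); the 2-D configuration at
Tmax = 500 improves on the initial best by more than 10 orders of magnitude.

## Classifier and losses

The trunk is a 16-block inverted-residual stack (expand 1×1 → depthwise 3×3 →
linear project, ReLU6, batch norm, identity skips where shapes allow) behind a
3×3 stride-1 stem. All stride-2 steps act on the 26-row time axis only, so the
3-wide feature axis never collapses (rows 26→13→7→4→2). The head is a 1×1
projection to 32 or 64 features, global average pooling, one hidden dense
layer, dropout, and a 4-way softmax. At width multiplier 1.0 the model has
~315k parameters; the desk-scale configuration (width 0.25, expansion 2,
32-wide head) has ~19k. Training is from scratch — a 26×3×1 input cannot
consume 3-channel natural-image weights, so there is no transfer learning.
The network and its backpropagation are implemented directly in numpy
(float32, im2col convolutions, Adam); gradients are verified against central
differences in the test suite.

Losses: plain categorical cross-entropy; weighted CE with the per-class
weight applied to the true class's log-probability; focal loss
(1 − p_true)^γ with γ = 2 by default. Adaptive class weights use per-class
*validation recall* (the published description does not fix the split or the
recall/precision choice): Mr_j = 1 − recall_j, w_j = α(Mr_j)/Σα(Mr_i) with
α(y) = e^y by default (identity, y³, e^100y and 10^y are available). A class
absent from an epoch carries its previous recall forward; when every class is
perfectly recalled and α(0) = 0, weights fall back to uniform. The default
training loss is adaptive weighted CE.

## Risk rules and event matching

Rain alerts require rainfall strictly above the 75th percentile of the
evaluation collection's biweekly values (population percentile; a per-site
option exists) during predicted flowering — fruit set is folded into the
flowering window, as the 4-class model has no separate fruit-set stage. Pest
alerts scan the 30 days before predicted veraison onset for T > 22 °C and
RH > 70%, collapsing consecutive qualifying days into one alert at the run's
first day. Matching is greedy one-to-one by smallest gap within ±5 days per
(site, type); unmatched events are false negatives; an unmatched alert is a
false positive only with no event within ±10 days, so alerts 5–10 days from
an event count neither way. Note the published validation table's precision
rows (0.79/0.74) are not reproducible from its own TP/FP counts (82/100 =
0.82, 64/83 = 0.77); this package reports the counts-derived values.

Synthetic "documented events" are derived from the ground-truth timelines
(true flowering ∧ high rain; true pre-veraison warm-humid runs) with ±2-day
reporting jitter, so alert sensitivity on synthetic data measures how well
*predicted* phenology aligns risk windows with *true* phenology.

## Scaled-down study conditions

The end-to-end run uses 400 clean sites (40/30/30 zone mix), a 70/30
site-grouped zone-stratified split with 20% of training sites held out for
validation, tuning with N = 10 agents for Tmax = 20 iterations, and the
width-0.25 network. Candidate fitness is the validation loss after 8 gradient
steps on a 320-sample proxy subset (fixed step count keeps fitness cost flat
across batch sizes; the decoded epoch count applies to the final fit, whose
search range is narrowed to 6–16 epochs at this problem size). These sizes
are the package's defaults for a single-core desk run; the thresholds the
tests assert (≥85% interval accuracy, median onset error ≤14 days) were
calibrated once under these conditions and are far below what the same code
achieves at larger scale.

## Known limitations

- The synthetic generator's realism limits (above) bound what green tests
  mean; no claim is made about real-sensor performance.
- Batch-norm statistics make training-mode and inference-mode outputs differ
  slightly; all reported metrics use inference mode.
- The ablation harness enumerates the 2×2×2 grid but model (re)training cost
  is the caller's budget; the test suite exercises it with a plug-in stub.
- Five-fold assignments partition the training portion only; the 30% test
  set is held out throughout.
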