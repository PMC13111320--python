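# vitiphen

Grapevine phenology staging from satellite vegetation-index time series, with
metaheuristic hyperparameter tuning and rule-based rain/pest risk alerting.

## The problem

Vineyard management in double-cropping grape systems hinges on knowing *when*
each developmental stage — budburst, flowering, veraison, harvest — occurs at
each site: rain during flowering ruins fruit set, and warm-humid spells in the
month before veraison favour grapevine moth (*Lobesia botrana*) outbreaks.
`vitiphen` turns per-site seasonal observations (biweekly NDVI and EVI, daily
rainfall, temperature and relative humidity) into per-interval stage
classifications, stage-onset dates, and actionable risk alerts.

The package is aimed at agricultural remote-sensing researchers: every
component — from the synthetic data that emulates the statistical structure of
satellite pixel time series to the evaluation harness — is a first-class,
seeded, testable module.

## Method

- **Labels from thermal time.** Ground-truth stages come from accumulated
  growing degree days, GDD(d) = Σ max(0, T − 10 °C); a stage's onset is the
  first day its threshold is crossed (budburst 50, flowering 400, veraison
  1000, harvest 1400 GDD).
- **Preprocessing.** NDVI spikes (|ΔNDVI| > 0.3 between observed biweekly
  steps) are censored; series contaminated beyond 30% are dropped; gaps are
  filled by length — linear (1 step), cubic spline (2–3), windowed LOESS
  (longer); rainfall is summed into 14-day intervals; features are min–max
  normalized, x′ = (x − x_min)/(x_max − x_min), with bounds fitted on training
  folds.
- **Pseudo-images.** Each site-season becomes a 26×3×1 matrix (rows =
  biweekly steps; columns = NDVI, EVI, rainfall); a causal cutoff at interval
  *t* zeroes later rows so predictions at *t* use only the past.
- **Classifier.** A MobileNetV2-style trunk of 16 inverted-residual blocks
  built on depthwise-separable convolutions (cost ratio Z_S/Z_N = 1/N +
  1/D_K²), global average pooling and a 4-way softmax head, trained with a
  class-weighted cross-entropy whose weights w_j ∝ α(1 − recall_j), α(y) =
  e^y, are recomputed every epoch from the validation confusion matrix. The
  network is implemented in numpy with manual backpropagation and runs
  comfortably on one CPU core at this input size.
- **Hyperparameter search.** The augmented dream optimizer: a population
  metaheuristic that alternates memory resets to group/global bests with
  cosine-decayed random "forgetting" of coordinates and dream-sharing copies,
  each proposal blended with a particle-swarm velocity update
  (α·x_DOA + (1−α)(x + v), α = 0.6). It tunes θ = {learning rate, batch size,
  dropout, kernel size, epochs}.
- **Risk rules.** Rain alert: interval rainfall above the 75th percentile
  during predicted flowering. Pest alert: T > 22 °C and RH > 70% within the
  30 days before predicted veraison. Alerts are validated against documented
  events with ±5-day matching (±10-day false-positive exclusion).

## Worked example

```python
from vitiphen.pipeline import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(n_sites=400, seed=1))
print(f"accuracy {res.interval_accuracy_pct:.1f}%  macro-F1 {res.macro_f1:.3f}")
print(f"median onset error {res.median_onset_error_days:.1f} days")
print("rain alerts", res.rain_alert_metrics)
print("pest alerts", res.pest_alert_metrics)
```

prints (seed 1, ~7 minutes on one CPU core):

```
accuracy 98.0%  macro-F1 0.966
median onset error 8.0 days
rain alerts {'sensitivity_pct': 100.0, 'precision': 0.98, 'f1': 0.99, 'tp': 50, 'fn': 0, 'fp': 1}
pest alerts {'sensitivity_pct': 69.2, 'precision': 0.77, 'f1': 0.73, 'tp': 229, 'fn': 102, 'fp': 67}
```

meaning: of the held-out sites' non-pre-season biweekly intervals, 98% are
assigned the correct stage; half of all stage-onset dates land within 8 days
of the thermal-time truth (onsets are quantized to interval midpoints, so
this is sub-interval precision); all rain-damage events and 69% of
pest-outbreak events derived from the ground truth are flagged within ±5
days — pest alerts are the harder target because a small veraison-onset
error shifts the whole 30-day scanning window. Numbers move a little across
seeds; see `docs/methods.md` for what the synthetic conditions do and do not
show.

The same workflow is scriptable from the shell:

```
vitiphen simulate --n-sites 400 --seed 1 --out data/
vitiphen preprocess --in data/ --out clean/
vitiphen tune --data clean/ --pop 10 --tmax 20 --seed 42 --out tune.json
vitiphen train --data clean/ --theta tune.json --seed 42 --out model/
vitiphen predict --model model/ --data clean/ --out preds.csv
vitiphen alerts --preds preds.csv --data clean/ --out alerts/
```

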