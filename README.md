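# nirsglm

Systemic-physiology correction and GLM inference for functional
near-infrared spectroscopy (fNIRS), with a semisynthetic ROC harness that
quantifies how well each correction separates evoked brain responses from
scalp physiology.

## The problem

fNIRS measures cortical hemoglobin changes through the scalp, so every
channel is contaminated by cardiac (~1 Hz), respiratory (~0.2-0.3 Hz) and
blood-pressure/Mayer-wave (~0.1 Hz) oscillations plus slow vascular drift
— signals that originate in skin, not brain. Naive regression treats this
structured noise as white and produces wildly overconfident statistics.
This package is for methodologists and analysts who need (a) the standard
corrections under one roof and (b) a way to measure their
sensitivity/specificity consequences.

Two families of corrections are implemented:

* **Prefilters** applied before statistics: spatial PCA (fit on the task
  file or a separate baseline file, removing components that explain 80%
  of the spatial covariance), projection of short-separation (SS, scalp
  only, ~7.5 mm) channel time courses out of long-distance (LD, ~30 mm)
  channels, and an image-reconstruction variant
  `Yf' = [I - LS(S'L'LS + lam I)^-1 S'L']Y'` using an approximate skin
  forward model `L` and smooth spatial basis `S`.
* **Statistical models**: the GLM
  `y = X_task b + X_short g + e`
  solved by OLS, by AR-IRLS (iteratively reweighted robust regression with
  AIC-selected autoregressive prewhitening of both sides), or by a
  mixed-effects AR-IRLS in which the SS coefficients of all channels share
  a zero-mean normal prior whose scale is pooled across the probe via
  `sigma = 1.4826 x MAD`.

The evaluation engine injects canonical hemodynamic responses at a
controlled contrast-to-noise ratio (CNR = peak / robust SD) into exactly
half of the LD channels of synthetic resting or breath-hold scans, runs any
pipeline combination, and pools per-channel p-values into ROC curves, AUC,
partial AUC (FPR <= 0.05), DeLong and bootstrap comparisons, and type-I
calibration curves.

## Worked example

Null calibration — the reason prewhitening exists. Generate 20 synthetic
resting scans with *no* evoked response, fit the task GLM, and count how
often each solver claims significance at p < 0.05:

```python
import numpy as np
from nirsglm.roc_harness import type_one_error_study

pooled = type_one_error_study(n_iterations=20, master_seed=1)
for name, p in pooled.items():
    print(f"{name:12s} FPR at p<0.05: {100 * np.mean(p < 0.05):5.1f}%  (n={len(p)})")
```

```
ols          FPR at p<0.05:  75.2%  (n=440)
ar_irls      FPR at p<0.05:   3.2%  (n=440)
ar_irls_ss   FPR at p<0.05:   5.7%  (n=440)
```

OLS rejects the true null on three quarters of the channels — the serially
correlated drift masquerades as activation — while the AR-prewhitened
robust solver stays near the nominal 5%, with or without the 16
short-separation nuisance regressors.

A single simulated scan end to end:

```python
from nirsglm import default_probe
from nirsglm.synthetic_data import NoiseSpec, make_events, generate_noise_scan, inject_response
from nirsglm.glm_engine import DesignMatrix, build_task_design, build_ss_design, ar_irls_fit

geom = default_probe()                      # 22 LD + 8 SS channels
noise = NoiseSpec()                         # 300 s at 7.8125 Hz
events = make_events("bh_random", noise.duration, seed=7)
scan = generate_noise_scan(noise, events, seed=7, geometry=geom)
scan, truth = inject_response(scan, events, cnr=0.7, seed=7, geometry=geom)

xtask, labels = build_task_design(events.stim, scan.n_time, scan.fs)
xshort, slab = build_ss_design(scan, geom, mode="both", decorrelate=True)
design = DesignMatrix(xtask=xtask, task_labels=labels, fs=scan.fs,
                      xshort=xshort, short_labels=slab)
results = ar_irls_fit(scan.select(geom.ld_indices()), design)
hits = [r.channel for r in results["HbO2"] if r.p[0] < 0.05]
print("channels called active:", hits)
```

```
channels called active: [0, 1, 4, 6, 8, 9, 11, 12, 13, 15, 16, 17, 18, 21]
```

Eleven of the 22 LD channels carry an injected response at CNR 0.7 in this
scan (channels 1, 4, 6, 8, 9, 11, 13, 15, 16, 17, 21); the solver recovers
all eleven and adds three false positives — breath-hold physiology at this
contrast is hard, which is exactly what the ROC harness quantifies.

The same pipeline grid is available from the shell: `nirsglm simulate`
writes a SNIRF scan with a truth-label sidecar, `nirsglm run` fits one
pipeline on one scan, `nirsglm roc` runs a benchmark grid (the full
3 x 4 x 5 = 60 combination grid with `--full-grid`), and `nirsglm report`
renders ROC/calibration plots.

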