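# Methods

`nirsglm` implements and benchmarks corrections for systemic physiological
contamination in functional near-infrared spectroscopy (fNIRS). This note
documents the models, the synthetic data they are evaluated on, the
numerical choices, and the limits of what the benchmarks demonstrate.

## Signal model and conversions

An fNIRS channel is a source-detector pair measured at 760 and 850 nm.
Long-distance (LD) channels (~30 mm separation) sample cortex plus scalp;
short-separation (SS) channels (~7.5 mm) sample scalp only. Raw intensities
are converted to optical density as `OD(t) = -log(I(t)/I0)` with `I0` the
temporal mean of the log-intensity (the geometric mean). Normalising in the
log domain makes OD exactly zero-mean over time, so intensity synthesis and
hemoglobin recovery compose to the identity for time-centred concentration
inputs; an arithmetic-mean normalisation would leave an offset of order
`var(OD)/2`. The modified Beer-Lambert law converts OD pairs to
oxy-/deoxy-hemoglobin concentration changes (HbO2, Hb, in uM) using the
Gratzer/Prahl molar extinction coefficients at 760/850 nm (HbO2 586/1058,
Hb 1548.52/691.32 cm^-1 M^-1) and a differential pathlength factor of 6.0
at both wavelengths. These constants are configuration values; any
consistent convention only rescales the regression coefficients and cancels
in ROC ranking.

The default probe replicates a motor-cortex layout: 8 sources and 7 LD
detectors on a 4x4 checkerboard grid with 30 mm pitch (one corner detector
omitted), giving exactly 22 LD channels, plus one 7.5 mm SS detector per
source mounted on the bundle holder slightly out of the scalp plane. The
placement puts every LD channel's nearest SS channel midpoint between 13.4
and 15.5 mm away, matching the published range for this cap. Channels are
classified SS when their source-detector distance is strictly below 15 mm.

Signal quality is summarised by the scalp coupling index (SCI): the
zero-lag Pearson correlation of the two band-limited (0.5-2.5 Hz,
around the cardiac rhythm) wavelength traces of a channel, with the
conventional acceptance threshold of 0.8. Zero-lag correlation was chosen
over a max-lag cross-correlation as the simplest testable reading; both are
in use in the field.

## Superficial filters

All prefilters are linear operators on the channel dimension, fit and
applied separately per chromophore:

* **PCA / baseline-PCA** — SVD of the time-centred data; the removed
  component count is the smallest number explaining at least 80% of the
  spatial covariance (squared singular values). `bpca` fits components on a
  separate baseline scan and projects them out of the task scan; `pca` uses
  the task scan itself. The 80% rule is applied uniformly to both variants.
* **SS unconstrained projection** — `Yf = (I - Xs(Xs'Xs)^-1 Xs')Ylong`, the
  least-squares projection of the SS time-course span out of the LD data.
* **SS image-reconstruction filter** —
  `Yf' = [I - A(A'A + lam I)^-1 A']Y'` with `A = L S`. The skin
  sensitivity matrix `L` is approximated analytically rather than by photon
  transport: a channel's sensitivity to a skin node is a Gaussian in the
  node-to-midpoint distance (width 10 mm) scaled by a partial-pathlength
  factor (SS 1.0, LD 0.3); only the relative SS/LD skin weighting matters
  for the filter's behaviour. Skin nodes form a 10 mm lattice over the
  probe's bounding box padded by 20 mm; the smoothing basis `S` holds
  unit-norm Gaussian kernels (width 15 mm) on a coarser 30 mm lattice
  restricted to the probe footprint, which keeps the basis genuinely
  low-spatial-frequency and `L S` full column rank. `lam` defaults to
  0.01 x the largest eigenvalue of `(LS)'(LS)`.

## GLM solvers

The task design convolves the stimulus boxcar with a canonical double-gamma
HRF (gamma-density difference, peak ~6 s, undershoot ~16 s, ratio 1/6) and
normalises each column to unit peak. SS nuisance blocks are z-scored SS
time courses (either chromophore or both), optionally replaced by their
orthonormal principal components to remove collinearity among SS channels;
task and SS regressors are never mutually orthogonalised.

* **OLS** — classical least squares with Student-t inference. Included as
  the baseline whose type-I error collapses under serially correlated
  noise.
* **AR-IRLS** — iterates (a) Tukey-bisquare robust regression (tuning
  constant 4.685, scale 1.4826 x MAD of residuals), (b) an AR(p) fit to the
  residuals with p chosen by AIC over 1..ceil(4 fs) (= 32 lags at
  7.8125 Hz), and (c) whitening of both y and X by the AR filter, until the
  coefficients change by less than 1e-4 relative (10 iterations cap).
  Inference runs on the whitened robust fit.

  Two inference details matter for calibration. First, the covariance of
  the robust estimate uses the Huber sandwich,
  `cov = [sum psi^2/(n-k)] / [mean psi']^2 (Xw'Xw)^-1`; the naive
  weighted-residual variance systematically understates uncertainty and
  inflates t even on clean normal noise. Second, the AR model is fit to a
  design-corrected residual spectrum: residuals are `(I-QQ')eps` for an
  orthonormal design basis Q, so their periodogram is biased low by the
  factor `1 - sum_j |F(q_j)(f)|^2/n` exactly at the frequencies where the
  design has spectral mass. Without this correction, whenever slow
  physiological drift happens to align with the task regressor, the
  regression absorbs that noise mode, the residual-based AR model
  understates noise power at the task band, and the test becomes
  anti-conservative. The corrected autocovariance feeds a Levinson
  recursion; when no design is supplied the Burg lattice is used (Burg
  keeps near-unit-circle poles — very slow drifts — far better than
  Yule-Walker). Effective degrees of freedom are taken as
  `sum(robust weights) - rank(X)`, an interpretation documented here since
  no exact convention exists after prewhitening plus reweighting.
* **Mixed-effects AR-IRLS** — treats the SS coefficients Gamma of all
  channels as draws from a common zero-mean normal prior `N(0, sigma^2)`
  pooled across the probe. EM-style outer loop: each channel solves a
  ridge-penalised whitened robust regression with penalty rows
  `(sigma_eps/sigma) I` on the Gamma block only (task coefficients are
  never penalised), where `sigma_eps` is the channel's residual scale from
  the unpenalised pass — the exact ridge implied by the prior against noise
  `N(0, sigma_eps^2)`. A dimensionless `1/sigma` penalty would make the EM
  collapse: with orthonormal SS columns the shrinkage factor becomes
  `sigma^2/(1+sigma^2)` and the scale update has no real fixed point.
  `sigma` is updated as 1.4826 x the median of |Gamma| pooled across
  channels — the robust scale about zero, keeping the prior zero-mean (the
  1.4826 factor is the median-consistency constant, so the median absolute
  deviation is used; about zero rather than about the sample median because
  the prior mean is fixed at zero). The loop stops when sigma changes by
  less than 0.1% (20 iterations cap; floor 1e-6 with a warning). The AR
  filters and robust weights from the initial unpenalised pass (sigma =
  infinity, which reproduces plain AR-IRLS with the SS columns appended)
  are held fixed during the sigma iterations — an EM with fixed working
  covariance — which keeps the iterative model affordable.

The joint HbO2/Hb test is Hotelling's T^2 on the task-coefficient pair with
a diagonal 2x2 covariance (the chromophores are fit independently) and an
F-transform p-value. All p-values are two-sided and uncorrected; the ROC
harness consumes raw p-values.

## Synthetic data

No recordings ship with the package; the generator emulates the statistical
structure the benchmark needs:

* a shared superficial signal g(t) per chromophore: an AR(1) drift with
  coefficient 0.98 at 7.8125 Hz scaled to stationary SD 1.0 uM, plus
  cardiac (1.0 Hz, amplitude 0.3), respiratory (0.25 Hz, 0.2) and
  Mayer-wave (0.1 Hz, 0.5) sinusoids with random phases and slowly
  wandering amplitudes (+-30% at 0.005-0.02 Hz);
* SS channels observe `a_i g(t)` (gains uniform in 0.8-1.2) plus sensor
  noise (SD 0.1); LD channels observe `m_j g_j(t)` plus white noise (SD
  0.2), where `g_j` is an independent realisation of the same process mixed
  so that `corr(g_j, g) = 0.85` — SS regression can help but can never be
  perfect;
* the Hb block is the HbO2 block scaled by -1/3 plus proportional noise;
* breath-hold conditions add a smooth biphasic vasomotor bump
  (gamma-difference, peak ~15 s, width ~20 s, amplitude 2 x drift SD) at
  the block schedule (25 s hold / 30 s rest, 5 blocks after a 30 s
  lead-in). `bh_locked` sets stimulus onsets equal to the holds;
  `bh_random` and `rest` draw stimulus onsets with 25 s duration and
  inter-stimulus intervals uniform on 15-50 s.

The drift dominates the white noise deliberately: that is the regime in
which OLS shows the gross type-I inflation that motivates prewhitening.
Scans default to 300 s at 7.8125 Hz on the 22 LD + 8 SS replica probe.

Evoked responses are injected into a uniformly random half of the LD
channels only (never SS): the unit-peak canonical-HRF regressor scaled per
channel and per chromophore so that peak amplitude equals
CNR x 1.4826 x MAD of the pre-injection data — positive for HbO2, negative
for Hb. Because the Hb noise is ~1/3 of HbO2, per-species CNR scaling
automatically yields a ~-1/3 Hb/HbO2 response amplitude ratio. The default
CNR is 0.7.

What the generator does not emulate: motion artifacts, subject-to-subject
variability, heteroscedastic optode coupling over time, heart-rate
variability of the cardiac peak, or task-evoked changes in systemic
physiology beyond the breath-hold bump. Passing benchmarks here show the
estimators behave correctly under stationary, Gaussian-ish, strongly
serially correlated physiology — not that they are robust to artifacts or
nonstationarity in real recordings.

## ROC harness

Each iteration generates a scan for one condition, injects at the given
CNR, applies one prefilter, solves one GLM, and emits per-channel p-values
for HbO2, Hb and the joint test. Decisions are pooled across iterations
and channels before curve construction. ROC curves rank by `1 - p`; AUC is
the trapezoidal area (equal to the Mann-Whitney probability). Partial AUC
restricts to FPR <= 0.05 with linear interpolation at the cut and
normalises by the interval width (raw 0.016 <-> normalised 0.32). AUC
differences are compared with DeLong's placement-value test (midrank
implementation); pAUC differences with an iteration-level bootstrap and a
Student-t tail on the observed difference over the bootstrap spread.
Type-I calibration curves plot the empirical FPR on noise-only channels
against the nominal threshold.

The full grid — 3 conditions x 4 preprocessings (none, PCA, bPCA,
SS-projection) x 5 GLM variants (OLS and AR-IRLS each with/without SS
regression, plus mixed-effects with SS) — expands to the 60 pipeline
combinations. Desk-scale defaults are 200 iterations per pipeline
(AUC stable to about +-0.02); the published-scale 1650 iterations are a
flag away. Per-iteration seeds are master + iteration index; every stage
of an iteration draws from an independent child of that seed, so runs are
bit-for-bit reproducible. Failed iterations are excluded and counted,
never imputed.

## Known limitations

* The skin forward model is a geometric surrogate; absolute units of the
  image-reconstruction filter are not physically meaningful, only its
  projection behaviour.
* At very short scans (n below a few hundred samples) the AIC search over
  32 AR lags overfits and the t reference degrades; the solvers are meant
  for full-length scans.
* Under the strong-drift null, AR-IRLS retains a small residual type-I
  excess (a few percentage points above nominal at p < 0.05) traceable to
  noise-model estimation uncertainty at the task frequencies; an oracle
  GLS with the known noise spectrum is exactly calibrated, and the
  design-corrected AR spectrum removes the first-order part of the gap.
* The mixed-effects EM holds whitening and robust weights fixed after the
  first pass; a full re-estimation per sigma step would be slower and was
  not observed to change the pooled scale materially.
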