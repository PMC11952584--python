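# Methods

## Signal model and conventions

A time-density curve (TDC) is the mean contrast density over a region of
interest of a DSA sequence, sampled uniformly: sample `i` sits at
`t0 + i·dt`, times in seconds, densities in arbitrary units. The ROI
statistic is the arithmetic mean, so curves do not depend on ROI size.
Contrast density is physically non-negative; wherever a correction could
produce negative values they are clamped to zero.

The aneurysm dome is treated as a causal linear time-invariant system driven
by the arterial input function (AIF) `C_a` measured at the parent artery:
`Q = C_a ∗ h`, discretely `Q_i = dt·Σ_{j≤i} C_a[i−j] h[j]`. The impulse
response `h` (units 1/s) carries the aneurysm's intrinsic hemodynamics;
everything operator-dependent (injection strength, rate, timing) lives in
`C_a`. The assumptions are the usual ones for indicator-dilution analysis:
linearity of density in contrast concentration, time invariance over one
acquisition, and a shared grid for inlet and dome curves (`resample`
provides linear-interpolation regridding when acquisitions differ in frame
rate).

## Deconvolution

`build_toeplitz` assembles the discrete convolution operator
`A[i, j] = dt·C_a[i−j]` (lower-triangular Toeplitz; plain, not
block-circulant — no delay-insensitive variant is attempted). `deconvolve_svd`
inverts it by truncated SVD: singular values below
`truncation_fraction × σ_max` are zeroed before pseudo-inversion. The default
truncation fraction is 0.15, the middle of the 10–20 % convention in SVD
perfusion deconvolution; it is the main noise/bias trade-off knob. Lower
values sharpen the recovered response but amplify noise; higher values bias
peak height down and the full width at half maximum (FWHM) by up to ~10 %
for wide injection boluses.

Two numerical guards apply regardless of configuration:

* a machine-rank floor of `N·eps·σ_max` is always enforced, because the
  operator of any causal AIF (first samples zero before bolus arrival) is
  exactly rank-deficient and its null-space singular values must never be
  inverted, even with truncation 0;
* negative recovered impulse-response samples are clamped to zero by default
  (`regularize_negative_irf`), which can be disabled to obtain the raw
  algebraic least-squares solution.

With truncation 0 and a noiseless, well-conditioned system the composition
deconvolve∘convolve is the identity to better than 1e−6; the acceptance
script measures this on every run.

## Standardized injection and Q_new

The standardized injection is a peak-normalized gamma-variate bolus

    g(t) = A·((t−t_d)/(αβ))^α · exp(α − (t−t_d)/β),  t ≥ t_d,

which attains its peak value `A` exactly at `t = t_d + αβ`. Defaults:
A = 1 a.u., t_d = 0.5 s, α = 3, β = 0.4 s, duration = acquisition span. The
gamma-variate is the standard parametric bolus model; the exact profile is a
configuration knob since any fixed choice yields injection-invariant output.
`correct_tdc` composes pedestal removal → truncated-SVD deconvolution →
reconvolution with the standardized injection, giving the
injection-invariant dome curve `Q_new`. No AUC-preserving rescaling of
`Q_new` is applied: rescaling to the observed curve's area would reintroduce
the injection dependence the correction removes.

### Pedestal handling

DSA curves carry a pre-bolus pedestal. `baseline_correct` subtracts the mean
of the first `n_baseline` samples (default 3) and clamps negatives. Inside
`correct_tdc` the handling is noise-adaptive, because on noisy curves the
3-frame mean is itself the single largest error source of the whole
correction (its standard error, σ/√3, is ~3 % of peak at curve SNR 20 and
propagates almost 1:1 into peak height):

* the noise level is estimated robustly from second differences
  (`1.4826·median|Δ²v|/√6`), which is insensitive to the smooth bolus;
* if the curve is effectively noiseless (estimate < 1e−4 of range), the
  plain first-`n_baseline`-frame mean is used — this keeps noiseless
  algebraic identities exact;
* otherwise the AIF pedestal is averaged over all quiet frames (pre-arrival
  head before the smoothed curve reaches 20 % of range, plus the
  post-washout tail after it falls below 2 % — an arterial bolus returns to
  baseline), and the dome pedestal is profiled out in closed form as a
  nuisance parameter: the component of the dome curve lying in the residual
  space of the truncated operator (which no retained singular mode can
  represent) is attributed to a constant pedestal,
  `c = ⟨(I−P)𝟙, (I−P)q⟩ / ‖(I−P)𝟙‖²` with `P` the projector onto retained
  left singular vectors. When the residual space is numerically empty the
  head-frame mean is used instead.

Setting `n_baseline = 0` disables all pedestal handling; the synthetic
cohort analyses do so because the generative model simulates no pedestal
(see below).

## QA biomarkers

All parameters are extracted from a single curve (plus a reference for the
correlation index):

* **BAT** — time of the first sample strictly exceeding 1 % of peak
  ("strictly exceeds" makes the tie-break deterministic).
* **TTP / PH** — time of the first attainment of the maximum, and the
  maximum.
* **MTT** — FWHM at PH/2; crossings located by linear interpolation between
  bracketing samples (sub-frame precision). A curve that never falls below
  half maximum after the peak closes its window at the last sample and is
  flagged (`fwhm_window_open`), not errored.
* **Max-Df** — maximum forward difference `(v[i+1]−v[i])/dt` on [BAT, TTP];
  a single-sample window returns 0.
* **AUC** — trapezoidal integral over the acquisition; **AUC-k** integrates
  from BAT to `BAT + k·MTT` for k ∈ {0.5, 1, 1.5, 2}, with the partial last
  trapezoid interpolated. Windows anchor at BAT by default (configurable to
  acquisition start); anchoring at arrival makes the windows
  delay-invariant.
* **Cor** — maximum over non-negative lags of the Pearson correlation
  between the standardized AIF and the dome curve (the dome cannot lead the
  inlet), overlap ≥ 5 samples; an optional `max_lag` caps the scan.

Relative (post/pre) parameters are fieldwise ratios; any pre-treatment
denominator with magnitude below a floor (default 1e−6 in native units)
yields NaN rather than ±infinity, and downstream modelling drops such rows
explicitly.

## Synthetic cohorts

The generator produces the ground-truth world the pipeline is meant to
invert, and is a pure function of (spec, seed) — reruns are byte-identical.

* **Impulse responses**: exponential (default), boxcar, or dispersed-gamma
  residue shapes, parameterized by true transit time and gain, normalized so
  `∫h dt = gain`.
* **Injections**: gamma-variate boluses with log-normal amplitude
  (σ = 0.35) and width (σ = 0.25) jitter and uniform delay on [1.0, 2.0] s —
  DSA always records mask frames before contrast arrival, so a ≥1 s quiet
  period is realistic. "Heavy variability" scenarios raise the two sigmas to
  0.6/0.4 (amplitudes spanning roughly 0.3–3×).
* **Acquisition noise**: iid Gaussian per curve with σ = clean dome peak /
  SNR, default SNR 20. No pedestal is simulated — the model is exactly
  `Q = h ∗ C_a + ε` — which is why the cohort analyses run with
  `n_baseline = 0`.
* **Outcomes**: true class ~ Bernoulli(prevalence 0.25, the middle of the
  20–30 % background rate of incomplete occlusion). Occluded aneurysms draw
  post/pre gain ratios from N(0.45, 0.15), failures from N(0.9, 0.15)
  (truncated positive); a weaker secondary effect moves the transit-time
  ratio (N(0.95, 0.15) vs N(1.15, 0.15)). This places the predictive signal
  chiefly on PH/AUC-type ratios, with MTT/TTP weaker. Labels are then
  flipped independently with probability 0.15, which caps the achievable
  AUROC near 0.8 rather than 1.0 — a realistic difficulty. Label 1 encodes
  failure to occlude and is the positive class everywhere.
* **Oracle**: because the latents are class-conditionally Gaussian, the
  Bayes-optimal score has a closed form; `oracle_auroc` integrates it by
  direct Monte Carlo (200 000 draws) including the label flips. The MCCV'd
  network is expected to land within a few hundredths of this ceiling.
* **Image stacks**: `gen_image_stack` renders two curves as disjoint
  rectangular blobs with optional pixel noise, so ROI-mean extraction can be
  exercised end-to-end against a round-trip oracle.

What the generator does **not** emulate: recirculation humps in the AIF,
motion artifacts, partial-volume effects at the inlet ROI, foreshortening of
the 2-D projection, inter-reader ROI variability, or demographic covariates.
Passing tests on these cohorts therefore demonstrate correctness of the
inversion and modelling machinery under the stated signal model, not
clinical performance.

## Outcome classifier

A deliberately small dense network implemented directly in numpy: input
dense layer and one hidden layer, 256 Swish units each, L1-L2 kernel
penalties (defaults 1e−5/1e−4), 10 % dropout after the hidden layer, sigmoid
output; Adam (lr 0.001) on binary cross-entropy, batch size 32, at most 300
epochs with early stopping on validation loss (patience 15, best weights
restored) and learning-rate reduction ×0.1 after 3 stagnant epochs
(floor 1e−6). Weight init is seeded Glorot uniform; training is
deterministic per seed.

Features are z-scored with training-split statistics only — QA parameters
span orders of magnitude in native units and an unscaled fit would be
dominated by the largest one. The default feature set is the six relative
parameters (Cor, TTP, MTT, PH, AUC, Max-Df); the extended set adds the four
AUC windows. BAT is extracted but excluded from the default model features.

Evaluation: stratified 80/20 train/test split, the training side split 80/20
again into train/validation; Monte-Carlo cross-validation repeats this with
independent derived seeds (default 10 splits, fresh model per split, no
weight reuse) and reports mean ± sd of accuracy, AUROC (rank statistic,
midrank ties), sensitivity and specificity (positive class = failure,
threshold 0.5), plus per-split confusion matrices. Splits are by row id;
with multiple aneurysms per patient this would be an optimistic split and a
patient-id grouping should be added.

## Local explanations

`explain_case` perturbs a case with Gaussian noise scaled by per-feature
training standard deviations (2000 samples, row 0 unperturbed), scores the
black box, and fits a locality-weighted ridge regression (weights
`exp(−d²/w²)`, `w = 0.75·√n_features` in standardized space, ridge α = 1) of
the probabilities on standardized features. The reported contribution of
feature j is `coefficient_j × standardized value_j` — probability units,
oriented to the positive class: positive pushes toward failure to occlude.
Contributions are sorted by magnitude and truncated to the top six.
Perturbation is continuous; no quartile discretization is used, since all
model features are continuous ratios. On a purely linear-logit black box the
contribution signs match `coefficient × value` in ≈97 % of random cases.

## Problem sizes and numerical tolerances

The validation suite and the acceptance script run at desk scale, chosen so
the full suite completes in a few minutes on one CPU: acquisition grids of
76–201 samples (dt 0.1–0.2 s, spans 15–20 s), 200 patients for noisy
recovery, cohorts of 400–600 for MCCV (10 splits), 100 instances for
surrogate faithfulness. Algebraic identities are asserted at 1e−12 (operator
vs brute-force convolution), noiseless inversion at 1e−6, reconvolution at
1e−8, injection invariance at 1e−3 of peak with biomarker CVs below 0.5 %.

## Known limitations

* The truncation threshold is relative to σ_max; a discrepancy-principle
  (noise-scaled) threshold would adapt better across injection shapes but is
  deliberately out of scope.
* FWHM-based MTT inherits a downward bias of a few percent at truncation
  0.15 for wide boluses.
* Real AIFs include recirculation, which the gamma-variate standard
  injection and the quiet-tail pedestal window do not model; the tail window
  would need tightening on clinical data.
* The classifier is evaluated on synthetic cohorts only; no claim about
  clinical discrimination follows from these experiments.
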