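# angioqa

Injection-invariant quantitative angiography for aneurysm occlusion
prediction.

## The problem

After an intracranial aneurysm is treated with a flow diverter, roughly a
quarter of patients show incomplete occlusion at six months. Quantitative
angiography (QA) extracts hemodynamic biomarkers from time-density curves
(TDCs) of digital subtraction angiography (DSA) and can help predict that
outcome — but contrast is usually hand-injected, and differences in injection
strength, timing and duration swamp the biology. A curve measured after a
vigorous injection looks "better perfused" than the same aneurysm after a
gentle one.

`angioqa` removes that injection bias. The aneurysm dome is modelled as a
linear time-invariant system driven by the arterial input function (AIF)
measured at the parent artery:

    Q(t) = (C_a * h)(t)          Q_i = Δt · Σ_{j≤i} C_a[i−j] · h[j]

The dome's impulse response `h` is recovered by inverting the
lower-triangular Toeplitz convolution operator `A` built from the AIF, using
a truncated singular value decomposition

    A = U Σ Vᵀ,   h = V Σ⁺_trunc Uᵀ Q,

where singular values below a fraction (default 0.15) of the largest are
discarded to suppress noise amplification. Reconvolving `h` with one fixed
gamma-variate bolus — the standardized injection — yields an
injection-invariant dome curve `Q_new`, as if every patient had been injected
by the same machine.

From `Q_new` the package extracts the QA biomarkers — bolus arrival time
(BAT, first sample above 1 % of peak), time to peak (TTP) and peak height
(PH), mean transit time (MTT, full width at half maximum), maximum inflow
derivative (Max-Df), total and windowed areas under the curve (AUC,
AUC-0.5/1.0/1.5/2.0 over multiples of MTT), and the lag-scanned
cross-correlation (Cor) between the standardized AIF and `Q_new`. Treatment
effect is summarized as post/pre ratios of these parameters, which feed a
small dense network (two 256-unit Swish layers, L1-L2 regularization, 10 %
dropout, Adam, early stopping) that predicts the probability of **failure to
occlude** (label 1). Model quality is assessed by Monte-Carlo
cross-validation (repeated stratified 80/20 splits), and every prediction
can be explained by a LIME-style local surrogate: signed per-feature
contributions in probability units, truncated to the top six.

Because no imaging data ship with the package, a first-class synthetic
module generates the whole study from ground truth: impulse responses,
variable hand injections, noisy paired acquisitions, and outcome-labelled
cohorts whose separability is controlled by post/pre effect sizes.

## Worked example

One synthetic aneurysm with a strong treatment response (post/pre flow gain
0.45), imaged with a slow hand injection before treatment and a fast machine
injection after — the worst case for naive comparison:

```python
import numpy as np
from angioqa import (
    DeconvolutionConfig, InjectionParams, IrfSpec, PatientSpec, StandardInjection,
    correct_tdc, extract_all, gen_patient, relative_parameters, standard_injection,
)

dt, duration = 0.2, 15.0
patient = PatientSpec(
    irf_pre=IrfSpec("exponential", mtt_true=2.0, gain=1.0),
    irf_post=IrfSpec("exponential", mtt_true=2.2, gain=0.45),
    label=0, seed=42,
)
slow_hand = InjectionParams(amplitude=0.8, delay=1.6, beta=0.7, noise_sigma=0.01)
fast_machine = InjectionParams(amplitude=1.9, delay=1.1, beta=0.3, noise_sigma=0.01)
rec = gen_patient(patient, slow_hand, fast_machine, dt, duration)

std = StandardInjection(dt=dt, duration=duration)
reference = standard_injection(std)
cfg = DeconvolutionConfig(truncation_fraction=0.15, n_baseline=0)

qa = {}
for state in ("pre", "post"):
    q_new = correct_tdc(rec[f"ca_{state}"], rec[f"q_{state}"], std, cfg)
    qa[state] = extract_all(q_new, reference=reference)
    raw = extract_all(rec[f"q_{state}"])
    print(f"{state:4s}  raw PH {raw.ph:5.3f}  corrected PH {qa[state].ph:5.3f}"
          f"  corrected MTT {qa[state].mtt:4.2f} s")

rel = relative_parameters(qa["post"], qa["pre"])
print(f"post/pre corrected ratios: PH {rel.ph:.3f}  AUC {rel.auc:.3f}  MTT {rel.mtt:.3f}")
```

prints

```
pre   raw PH 0.523  corrected PH 0.504  corrected MTT 3.08 s
post  raw PH 0.334  corrected PH 0.206  corrected MTT 3.39 s
post/pre corrected ratios: PH 0.408  AUC 0.454  MTT 1.101
```

The raw PH ratio (0.334/0.523 ≈ 0.64) badly overstates residual filling
because the post-treatment injection was 2.4× stronger; the corrected ratio
0.41 is close to the true flow reduction of 0.45. On full synthetic cohorts
this translates directly into model quality: with heavy injection
variability, ten-split MCCV of the network reaches a mean AUROC of ~0.85 on
corrected relative features versus ~0.65 on uncorrected ones, and on the
default cohort the network comes within 0.01 of the generator's
Bayes-optimal AUROC (~0.79).

## Command line

```bash
angioqa simulate --seed 1 --out-dir runs/sim            # synthetic cohort + truth
angioqa correct  --inlet inlet.txt --dome dome.txt --out-dir runs/corr
angioqa extract  dome_qnew.txt --reference std_aif.txt --out params.csv
angioqa train    --cohort runs/sim/cohort.csv --out-dir runs/model
angioqa explain  --cohort runs/sim/cohort.csv --case-id 3 --out-dir runs/expl
angioqa run      --seed 1 --out-dir runs/full           # whole pipeline
```

Every command writes a `manifest.json` (config hash, seed, versions) so runs
are reproducible byte-for-byte.

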