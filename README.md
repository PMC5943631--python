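# wristbp

Calibration and validation analysis for wrist-cuff blood pressure monitors
against simultaneous intra-arterial reference pressures.

Automatic cuff devices are licensed against manual auscultatory readings,
not against the gold standard — direct intra-arterial pressure. A device
that is accurate "on average" can still misread individual patients by
10–15 mmHg, enough to leave truly hypertensive patients untreated (a
*treatment gap*). This package implements, as a tested and reusable
pipeline, the statistical machinery of a catheterization-lab validation
study of a wrist-worn oscillometric device:

* **Synthetic study generator** — no patient-level data are publicly
  deposited for studies of this kind, so the package ships a first-class
  generator: a cohort with realistic central/peripheral pressure
  distributions, beat-to-beat intraphysiological variability (~20/10 mmHg
  swing over 4 min), radial-vs-aortic systolic augmentation, a miscalibrated
  noisy wrist device that reports a per-reading SD, double-observer
  auscultatory readings, and the full two-day measurement protocol.
* **Protocol logic** — eligibility rules, the bilateral arm-equality screen
  (arms must agree within 10/5 mmHg), and assembly of simultaneous
  wrist/intra-arterial pairs with conditioning readings discarded.
* **Jackknife calibration** — leave-one-out fitting of per-channel affine
  calibration coefficients with honest held-out evaluation.
* **Bland–Altman agreement** — signed and absolute mean-difference families,
  limits of agreement, the a-priori 10/5 mmHg validity rule, paired testing,
  and pre/post improvement percentages.
* **Hypertension classification** — CHEP (≥135/85) and SPRINT (≥120) calls,
  2×2 concordance against the intra-arterial reference, treatment gap, and a
  one-tailed Fisher exact test.

## The statistics at the core

For N simultaneous pairs `(x_i, y_i)` of device output and reference
pressure, the jackknife calibration fits, at iteration i, ordinary least
squares of reference on device using the other N−1 pairs,

```
y = α_(−i) + β_(−i) x,     ŷ_i = α_(−i) + β_(−i) x_i ,
```

so every calibrated value `ŷ_i` is out-of-sample. Agreement between two
methods a and b is summarized from `d_i = a_i − b_i` and
`m_i = (a_i + b_i)/2` by the signed mean difference `d̄` with limits of
agreement `d̄ ± 1.96·SD(d)`, and by the **absolute** mean difference
`E|d|` with its own SD — the "bias" convention of device-validation work,
which cannot be averaged to zero by symmetric scatter. Calibration quality
is reported as `100·(AMD_pre − AMD_post)/AMD_pre` (accuracy improvement)
and the analogous reduction in SD of |d| (variability reduction). The
stand-in oscillometric front end builds a Gaussian-kernel amplitude
envelope peaking at the window's mean arterial pressure
(MAP = DBP + PP/3) and reads systolic/diastolic off at fixed amplitude
ratios (0.55/0.85).

## Worked example

`python examples/02_jackknife_calibration.py` simulates 20 patients under
the default miscalibrated device and calibrates the pooled wrist/intra-aortic
pairs:

```
pooled 40 wrist/intra-aortic simultaneous pairs

systolic:
  deployed model: calibrated = +19.58 + 0.851 x device   (n=40)
  held-out |error|: mean 8.63 mmHg (device raw: 8.37 mmHg)

diastolic:
  deployed model: calibrated = +17.99 + 0.605 x device   (n=40)
  held-out |error|: mean 4.10 mmHg (device raw: 13.88 mmHg)
```

The diastolic channel carries a ~+14 mmHg factory bias, and calibration
cuts its absolute error from 13.9 to 4.1 mmHg; the systolic channel is
nearly unbiased against the aorta to begin with (its miscalibration happens
to offset physiologic augmentation), so little improvement is available.
The other scripts in `examples/` walk through cohort synthesis, Bland–Altman
reporting, threshold classification, and the full pipeline
(`wristbp run --seed 1 --out out/` is the CLI equivalent of the last one).

## Layout

```
src/wristbp/     library (synth, protocol, calibrate, agreement, classify,
                 io, pipeline, cli)
examples/        one narrative script per capability
tests/           pytest suite (unit, property-based, acceptance)
scripts/         acceptance.py
docs/methods.md  modelling assumptions, defaults, and design choices
```
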