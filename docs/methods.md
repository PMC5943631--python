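# Methods

This note records the models behind `wristbp`, the defaults and why they
were chosen, and the design decisions taken where more than one reasonable
construction existed. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic cohort

Each patient profile draws demographics and true hemodynamics from
independent truncated normal marginals. Defaults describe a cardiac
catheterization population: central aortic systolic 133.4 (SD 22.0) mmHg on
[96.7, 179.3], aortic diastolic 67.4 (SD 8.7) on [50.6, 85.1], age 62
(SD 9) on [43, 77], BMI 30.6 (SD 5.7), wrist circumference 18.5 (SD 1.5) cm
on [15.5, 21.5] (inside the device's admissible 13.5–23 cm), 75% male, 75%
carrying a hypertension diagnosis.

Two non-obvious choices:

* **Moment-matched truncation.** Truncating N(μ, σ) to an asymmetric range
  shifts its mean (for the systolic marginal above, by about +1.3 mmHg).
  The generator instead solves for latent (μ, σ) such that the
  *post-truncation* mean and SD equal the configured values
  (`scipy.stats.truncnorm` moments + root solve), so large-sample summary
  statistics reproduce the configured table.
* **Prevalence by construction.** Exactly `round(0.75·n)` patients are
  flagged hypertensive — those with the highest mean aortic systolic
  pressure — so a 20-patient cohort always has 15/20 = 75% prevalence, and
  the flag correlates with pressure as a diagnosis would.

Radial-artery pressures are the aortic pressures plus a per-patient
augmentation offset: systolic mean +12.3 mmHg (between-patient SD 10),
diastolic mean −1.2 mmHg (SD 4, essentially no diastolic augmentation).
Peripheral systolic amplification is the reason calibrating to the radial
artery and to the ascending aorta are genuinely different analyses.

## Beat-to-beat variability

Within a session, both channels fluctuate around the patient's site means
as a single stationary AR(1) latent process with lag-1 correlation 0.7 at a
10-second lag (rescaled as `0.7^(step/10)` for other sampling steps),
scaled per channel. The marginal SDs default to 20/3.390 ≈ 5.9 mmHg
systolic and 10/3.390 ≈ 2.95 mmHg diastolic, where 3.390 is the expected
max-minus-min of 25 AR(1)(0.7) samples in units of the marginal SD
(measured once by direct simulation with 4×10⁵ replicates). This makes
the expected 4-minute swing at 10-second sampling ≈20 mmHg systolic and
≈10 mmHg diastolic. A single latent path drives both channels and both
sites, so windows cut at the same times are truly simultaneous; a pulse
pressure floor of 5 mmHg guards degenerate configurations.

The AR(1) is the simplest process with the right qualitative behavior —
slow wandering from respiration, vasomotion and autonomic tone. It does not
model waveform morphology, arrhythmia, or movement artifact.

## The wrist device

The real device's waveform-to-pressure algorithm is proprietary; the
package uses two documented stand-ins.

**Reading model (used by the study generator).** A reading senses one draw
from the beat window's distribution — `base ~ N(window mean, window SD)` —
because the cuff acquires over a sub-interval of a fluctuating window, not
over its exact mean. The output is `intercept + slope·base + N(0,
noise_sd)` per channel, and the reported per-reading SD is

```
sd = sqrt(slope² · window_SD² + noise_sd²),
```

the propagated physiologic variance plus device noise. Under this model the
reported SD equals the replicate SD of repeated readings on the same
window, which is what a reported measure of uncertainty should mean; with a
constant window and zero noise the reading is exactly the affine transform
of the window mean. Default miscalibration — systolic (−5, 0.95, noise SD
6), diastolic (+14, 1.0, noise SD 4) — is purely illustrative, chosen so
that pre-calibration absolute mean differences land in the low-teens regime
typical of a factory (auscultatory) calibration confronted with
intra-arterial truth. The wrist cuff senses the *radial* site; against the
aorta its raw systolic error is therefore small (the −5/0.95 miscalibration
happens to offset augmentation) while its diastolic error is large.

**Envelope model (explicit oscillometric front end).** For users who want
the mechanism visible: each beat contributes a Gaussian amplitude bump
centered at its MAP (= DBP + PP/3) with width PP/2; the envelope is the
mean bump, zeroed outside [min DBP − width, max SBP + width], with the
window's mean MAP anchored on the pressure grid so the peak sits exactly at
MAP. The fixed-ratio back end takes MAP at the argmax and reads systolic /
diastolic where the amplitude first falls to 0.55 / 0.85 of the peak
(standard literature ratios), linearly interpolating between grid points. A
monotone envelope (no interior peak) and crossings outside the deflation
grid are errors.

**Observers.** Auscultatory readings are the window mean plus Gaussian
observer error (default SD 4/3 mmHg), rounded to the nearest 2 mmHg with
halves away from zero (sphygmomanometer scale convention); two-observer
mode averages two independent observers. The upper-arm comparator used in
the classification analysis is derived from the aortic reference readings
by an affine bias model (default −12 mmHg systolic, −1.2 diastolic, noise
5/4), representing an arm cuff that cannot recover central systolic
pressure; deriving it at analysis time keeps the Day-2 schedule at exactly
ten readings per patient.

## Two-day protocol

Day 1: two observers take one auscultatory reading per arm; the screen
passes iff the arm-mean differences satisfy |Δsys| ≤ 10 and |Δdia| ≤ 5 mmHg
(closed bounds — "within ±X" is read inclusively). The comparison uses arm
means rather than observer-wise differences, mirroring the double-observer
intent; observers are compared per arm, not across arms. Four upper-arm
baseline readings follow. Day 2: two conditioning wrist readings (present
in the data, discarded by `assemble_day2_pairs`), then two wrist readings
simultaneous with intra-radial and two simultaneous with intra-aortic
readings. Simultaneity is implemented as an identical underlying beat
window per pair, and pairing is by order index within stage (the generator
guarantees consistency; the pairing rule is a package convention).
Intra-arterial references are the exact window means at their site — the
catheter is treated as noiseless truth.

Patients failing eligibility or the bilateral screen are excluded from all
downstream analyses, so a 20-patient run can legitimately analyse fewer
than 80 intra-arterial readings. The summary reports both the reading count
and the doubled channel-value count (systolic and diastolic tallied
separately), since both bookkeeping conventions appear in practice.

An independent double-observer auscultatory comparison set (default 375
measurements over 97 participants, allocated round-robin so per-participant
counts differ by at most one) is generated alongside, with auscultatory
readings modeled at the radial site.

## Calibration

`reference ~ intercept + slope·device` by ordinary least squares, each
channel independently, against either intra-arterial site. The affine
family is the minimal one expressing both offset and gain error; an
offset-only family (slope fixed at 1) is available as a configuration
point. The jackknife holds each pair out once, refits, and calibrates the
held-out device value; downstream agreement consumes only these held-out
values, so post-calibration statistics are honestly out-of-sample. The
*deployed* model is the full-data fit — the jackknife's role here is
evaluation, not model averaging — and applying it to a reading scales any
per-reading SD by the slope magnitude.

One subtlety: because the device value carries noise, the OLS slope is the
population *predictive* coefficient, which is attenuated relative to the
algebraic inverse of the device's miscalibration (classical
errors-in-predictor). That is the correct target for calibration — it
minimizes expected squared error of calibrated readings — so parameter
recovery is assessed against the population least-squares coefficients
(estimated by a large-sample simulation, 1500 patients) rather than
against the inverted device model. The acceptance suite checks that the
mean deployed coefficients over 200 replicate 20-patient studies recover
that estimand within 0.05 (slope) and 2 mmHg (intercept), and that
held-out absolute error shrinks after calibration in ≥95% of replicates on
every path whose raw bias exceeds 5 mmHg.

Calibration pools readings across patients (one population-level model per
channel and site), not per-patient coefficients.

## Agreement analysis

Implemented exactly as defined in the package README formulae. Choices:

* SDs use the n−1 denominator; limits of agreement use 1.96.
* The paired test defaults to the two-sided paired t; Wilcoxon signed-rank
  is available. Zero-variance conventions: all-zero differences give p = 1,
  constant nonzero differences give p = 0.
* The within-threshold comparison is inclusive (|d| = 10 counts as within
  10), and the validity rule defaults to requiring *all* pairs within
  threshold (required fraction 1.0, overridable).
* The trend slope is the least-squares slope of difference on pair mean; a
  zero-variance mean vector yields slope 0 by convention.
* Every measurement is treated as independent in p-values, including
  repeated measures from the same patient — this matches the study design
  being emulated but understates uncertainty; repeated-measures limits of
  agreement are a known extension, deliberately out of scope.
* Improvement percentages are reported unrounded, with
  half-away-from-zero integer rounding for display.

## Classification

CHEP = systolic ≥ 135 OR diastolic ≥ 85 (the home-monitoring confirmation
threshold); SPRINT = systolic ≥ 120, no diastolic criterion; both
config-overridable, bounds inclusive. The treatment gap is b/(a+b) — the
fraction of *reference-positive* measures the method calls negative —
identically 1 − sensitivity. Classification can be run per measurement or
per patient (averaging each patient's readings first); the grouping is an
explicit switch.

The one-tailed Fisher exact test conditions on both margins (hypergeometric
tail of the a-cell); the default direction is "method misses reference
positives". Note a structural property of margin-conditioning: a method
whose positives are a *subset* of the reference positives has its a-cell at
the top of its admissible range, so the undercall tail gives p = 1 — the
undercalling shows up in the margin, not the tail. The gap statistic, not
this p-value, is therefore the primary undercall measure; the "greater"
tail (association/sensitivity direction) is available as a parameter.

## What passing tests do and do not show

The generator reproduces the statistical *structure* the analysis assumes:
marginal pressure distributions, augmentation, AR(1)-correlated
within-session variability, affine device error with reported uncertainty,
observer rounding, and the pairing schedule. Passing tests therefore
validate the analysis machinery, not the device: real data add brachial
transfer physiology (not modeled — the upper-arm comparator is a flat bias,
and auscultatory readings sit at the radial site), waveform-morphology and
artifact effects, arm asymmetries, and drift between sessions. One visible
consequence: after central (aortic) calibration the simulated wrist agrees
*less* well with radial-site auscultatory references on the systolic
channel, because the calibration moves readings from the radial toward the
aortic scale; in the real study the corresponding independent-set systolic
improvement was modest for related reasons.

## Numerical conventions and problem sizes

Degenerate inputs raise informative errors (fewer than 2 pairs, zero device
variance, missing stages, undefined treatment gap); probability
conventions (p = 1) cover degenerate Fisher margins and zero-difference
paired tests. Seeds: every generator is a pure function of (inputs, seed),
accepting ints, `SeedSequence`s, or `Generator`s; composite simulations
spawn independent child streams per patient, so per-patient results do not
depend on cohort ordering upstream. The test suite uses 200 replicate
studies for the statistical guarantees and a 1500-patient pooled simulation
for the population-calibration oracle — sizes at which Monte-Carlo error is
far below the asserted tolerances while the whole suite runs in well under
a minute.
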