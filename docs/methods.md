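# Methods

## The cohort and the estimand

The packaged fixture is a 16-patient case series: emergency admissions
for citalopram or escitalopram exposure (12 intoxications, 4 therapeutic
users; 11 women, 5 men; ages 20–89) with an interpretable admission ECG.
Seven patients later developed ventricular tachycardia or fibrillation
(VT/VF); nine did not. Each record carries QRS, QT, QTc (ms) and heart
rate (bpm) as printed in the source tables, with missing dose and serum
values stored as missing (CSV empty cell / JSON null), never as zero.

The quantity of interest is the dimensionless ratio QRS/QTc. The analysis
contrasts its distribution between the VT/VF and no-VT/VF groups and
evaluates the fixed decision rule *high risk ⇔ ratio < 0.2*. The 0.2
threshold is imported from earlier hypothermia work on the same marker;
it is **not** estimated from this cohort, and the package deliberately
provides no machinery to fit it (with n = 16 any fitted threshold would
be decorative).

## Statistical conventions

**Two analysis modes.** Reproduction mode (the default wherever the
published numbers are at stake) uses the ratio values exactly as the
source printed them: half-up rounding of QRS/QTc at two decimals. General
mode uses full-precision quotients. The group means agree at printed
precision either way; fixing the convention makes the reproduction
checks exact rather than approximate.

**Population SD.** Descriptives are mean ± SD with divisor *n*
(population convention). This is an empirical identification: divisor
*n* reproduces every printed SD that can be reproduced at all (QTc
606 ± 78 / 508 ± 55, QRS 90 ± 14 / 122 ± 23, HR 85 ± 17 / 81 ± 25, age
43 ± 23, dose 1.59 ± 3.09, and the ECG-table bottom row), while divisor
*n − 1* reproduces none of the discriminating ones. Sample SD remains
available via `sd_mode="sample"`. One printed SD — 0.02 for the VT/VF
group's ratio — is not reproducible under either convention (both give
≈ 0.027, rounding to 0.03) and is treated as an erratum: the reproduction
checks compare the ratio means only.

**Test battery.** Per variable: Shapiro–Wilk normality per group,
Brown–Forsythe homogeneity (Levene with group medians as centers), then
a *pooled-variance* Student t-test, two-tailed, df = n₁ + n₂ − 2, at
α = 0.05. Student rather than Welch is deliberate — the published
pipeline gates on an equal-variance test and describes an unpaired
t-test; Welch is exposed as `welch_t_test` for sensitivity analysis. The
three tests delegate to `scipy.stats`; their contracts, not their
internals, are what the package guarantees. Degenerate inputs follow
explicit conventions: two spread-less groups give (F = 0, p = 1) for
Brown–Forsythe and (t = 0, p = 1) for the t-test when means agree; the
t-statistic is undefined (an error) when a zero pooled variance meets
unequal means.

One published claim does not survive recomputation: the QTc values of the
no-VT/VF group fail Shapiro–Wilk at the 0.05 level (p ≈ 0.010). The ratio
groups — the variable the headline result rests on — do pass (p ≈ 0.20
and 0.87). The pipeline reports all normality p-values rather than
gating on them.

**The t-test is cross-checked against an exact permutation test** in the
suite: all C(16,7) = 11,440 relabelings of the ratio column. The exact
permutation p (0.0007) and the parametric p (0.00037) agree to well
within the resolution these sample sizes allow and reach the same
decision at α = 0.01; the enumeration shares no code path with the
parametric test.

**Quantiles.** Box-plot summaries (median, 25/75 box, 5/95 whiskers) use
linear interpolation between order statistics (numpy's default, type 7).
The figures are presentational; no acceptance rests on them.

## QTc corrections and the consistency audit

Bazett (QT/√RR) is the default correction because it is identifiable
from the data: where the source derived QTc from an attached ECG, the
printed value matches Bazett recomputation from the printed QT and HR
within ~1 ms (cases 1, 3, 4, 12, 13 — exactly at the HR-60 case, where
every correction is the identity). Fridericia, Framingham and Hodges are
included for sensitivity analysis only.

`audit_qtc_consistency` recomputes QTc per case and flags discrepancies
beyond a tolerance (default 6 ms). On the fixture it flags cases 2, 10,
11, 14 and 16 — records whose reported QTc was taken verbatim from the
case report and evidently computed with a different (unstated)
correction or from a different beat; case 10's reported 535 ms is ~98 ms
above the Bazett value of its printed QT/HR pair. The audit is a
transcription/consistency QC tool, not a correction: reproduction-mode
statistics always use the printed values, because the published analysis
analyzed the reported numbers.

## Synthetic cohorts

The generator draws, per group, QRS ~ N(μ, σ²) truncated to [40, 300] ms
and QTc ~ N(μ, σ²) truncated to [200, 800] ms, independently; heart rate
is shared across groups, N(82, 22²) truncated to [30, 200] bpm. Defaults
are the case-series estimates (VT/VF group QRS 90/14, QTc 606/78;
no-VT/VF group QRS 122/23, QTc 508/55). QT is then defined by Bazett
inversion, QT = QTc·√(60/HR), so records never self-contradict; draws
where QT ≤ QRS or QT leaves [200, 800] are rejected and redrawn
(rejection sampling is exact and cheap at these scales; a hard cap of
10⁴ attempts per record turns a pathological spec into an error rather
than a hang).

Labels come either from group membership (`by_group`, the default — the
generator then emulates the observed two-group design) or from a
logistic model P(VT/VF) = expit(β₀ + β₁·ratio) with defaults anchored so
P ≈ 0.9 at ratio 0.15 and P ≈ 0.1 at 0.24, i.e. at the two observed
group means (β₁ ≈ −48.8, β₀ ≈ 9.52, stored in `_config.py`).

What the generator does *not* emulate: any QRS–QTc covariance (the
source reports none, so independence is the minimal assumption), any
dose→concentration→interval pharmacokinetics, demographics (placeholder
values), or non-Gaussian tails. Passing calibration tests therefore
show that the *pipeline* is sound — type-I error ≈ α under the null
spec (KS uniformity over 2,000 seeds), near-total power at the observed
effect size (pooled d ≈ 2.4 at n = 7/9), parameter recovery within
sampling error — not that real intoxication cohorts look Gaussian.

## ECG synthesis and delineation

Case reports often attach an ECG strip instead of printing intervals;
measuring that strip is a manual step this module reconstructs at desk
scale. A beat is a sum of Gaussian bumps (P, Q, R, S, T) with R
amplitude 1; beats repeat at RR = 60/HR over ≥ 5 beats (default 10) at
500 Hz, with optional additive white Gaussian noise.

The template is *calibrated against its own measurement convention*:

- QRS bounds are defined as the points where the absolute slope crosses
  5% of the per-beat maximum slope (constant in `_config.py`). The Q and
  S bump centres are solved (Brent root-finding, then one refinement
  pass against the composite beat's true maximum slope) so those
  crossings fall exactly at nominal onset and nominal onset + QRS.
- T-end follows the tangent method — the manual-measurement standard in
  QT research: the tangent at the steepest T downslope crossed with the
  isoelectric baseline. For a Gaussian bump that crossing sits at
  μ + 2σ, so the T centre is placed at onset + QT − 2σ_T, with
  σ_T = 0.12·(QT − QRS).
- The P wave is dropped whenever QT + 250 ms would reach the next beat's
  P position (T–P fusion at long QT / short RR); it carries no interval
  information here.

The delineator finds R peaks (relative-height peak picking), takes the
first/last suprathreshold slope samples in a ±110 ms window around R
with sub-sample linear interpolation of the crossing, locates T-end by
the tangent rule in (R + 120 ms, R + 0.8·RR), and reports medians over
beats (≥ 3 usable beats required; the median-over-beats convention is
this module's choice, as case reports state no protocol). All thresholds
are relative, making the result invariant to amplitude scaling. A 1-
sample Gaussian pre-smoothing and a noise floor estimated from the quiet
lead-in (threshold raised to 5× that floor when it dominates) keep the
delineator from latching onto noise; under noise the measured QRS
shrinks gracefully rather than failing.

Verified round-trip accuracy at noise 0 over QRS ∈ [70, 160] ms ×
QT ∈ [350, 700] ms at HR 75: worst-case error 1.8 ms (QRS) and 1.0 ms
(QT), against contract tolerances of ±10 and ±15 ms. The model makes no
claim of physiological realism (no baseline wander, muscle artifact,
U waves, or multi-lead logic); its purpose is to test the measurement
contract with exact ground truth.

## Problem sizes and determinism

The simulation-based checks use 2,000 seeds for null calibration, 1,000
replicates for power estimates, 500–10,000 records per group for
recovery, and a 20-point grid for waveform round-trips; together they
run in well under a minute on one core. Every stochastic component takes
an explicit integer seed (numpy `default_rng`; spawned child sequences
for replicate streams), so identical inputs give bit-identical outputs,
including the generated cohort CSVs and the reproduction report JSON.

## Known limitations

- n = 16, assembled from heterogeneous case reports with unstated
  measurement protocols; the reproduction is exact but the evidence
  remains case-series grade.
- The 0.2 threshold is imported, not validated; sensitivity/specificity
  on the fixture are in-sample numbers.
- Serum-concentration summaries in the source are internally
  inconsistent (the printed per-case values average neither the printed
  table mean nor the in-text mean); the fixture stores the per-case
  values and the package asserts nothing about serum means.
- The synthetic generator's independence and Gaussian assumptions are
  conventions, not estimates; treat simulation results as pipeline
  checks, not clinical claims.
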