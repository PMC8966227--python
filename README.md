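# qrsqtc

Analysis toolkit for the **QRS/QTc ratio** as an ECG marker of ventricular
arrhythmia risk (ventricular tachycardia / fibrillation, including torsade
de pointes) in patients exposed to the SSRIs **citalopram and
escitalopram** — whether through intoxication or therapeutic use.

Both drugs prolong cardiac repolarization (long QTc), but QTc alone
predicts torsade poorly. Because citalopram also blocks sodium channels at
high concentrations (widening the QRS complex, an effect thought to be
protective), the *ratio* QRS/QTc captures the imbalance between
depolarization and repolarization: low values flag patients whose QTc is
long *without* compensatory QRS widening, and such patients are the ones
who developed VT/VF in the published 16-patient case series that this
package reproduces. In that series the VT/VF group had markedly lower
ratios (0.15 ± 0.02 vs 0.24 ± 0.04, pooled two-tailed t-test
p < 0.0005), and every VT/VF case had a ratio ≤ 0.19; a threshold of 0.2
(imported from the hypothermia work that introduced the marker) separates
the groups with sensitivity 1.0 and specificity 8/9.

The package is aimed at clinical pharmacologists and biostatisticians who
want to (a) reproduce the published case-series analysis exactly, (b)
apply the interval metrics, statistics and threshold classifier to their
own cohort tables, or (c) stress-test the pipeline on synthetic cohorts
and synthetic ECG waveforms with known ground truth.

## What is implemented

- **Cohort data** (`qrsqtc.cohort`) — a validated case-level data model
  (demographics, exposure, ECG intervals, VT/VF outcome), lossless
  CSV/JSON I/O, and the full 16-case series shipped as a packaged
  fixture.
- **Interval metrics** (`qrsqtc.intervals`) — RR from heart rate, the
  Bazett / Fridericia / Framingham / Hodges QT corrections
  (QTc = QT/√RR for Bazett, the default), the QRS/QTc ratio with the
  half-up rounding the source tables use, and a QTc consistency audit
  that recomputes QTc from QT and HR and flags discrepant reports.
- **Group statistics** (`qrsqtc.stats`) — mean ± SD descriptives with the
  population-SD convention (divisor *n*, the convention that reproduces
  the printed values), Shapiro–Wilk, Brown–Forsythe, the pooled-variance
  two-tailed t-test (Welch as an option), and box-plot summaries
  (median, 25/75 box, 5/95 whiskers).
- **Risk classifier** (`qrsqtc.classifier`) — the strict
  ratio < threshold rule, confusion-matrix evaluation, and ROC-style
  threshold sweeps.
- **Synthetic cohorts** (`qrsqtc.synthetic`) — a truncated-Gaussian
  generator at the case-series group parameters with internally
  consistent intervals (QT back-computed by Bazett inversion), parameter
  recovery, and Monte-Carlo power simulation.
- **ECG synthesis & delineation** (`qrsqtc.ecg`) — a Gaussian-bump beat
  model with exact ground-truth intervals, and a delineator using
  derivative-threshold QRS bounds and the tangent method for T-end.
- **CLI & reproduction report** (`qrsqtc.cli`, `qrsqtc.report`) — the
  `qrsqtc` command with `reproduce`, `classify`, `audit`, `simulate` and
  `synth-ecg` subcommands.

## Worked example

Reproduce the published analysis from the packaged case series:

```sh
$ qrsqtc reproduce -o reproduction
all 27 reproduction checks passed; report in reproduction/
```

The checks recompute, at printed precision, every published number: the
four group comparisons (ratio 0.15 vs 0.24 with p < 0.0005; QRS 90 ± 14
vs 122 ± 23, p < 0.01; QTc 606 ± 78 vs 508 ± 55, p < 0.05; heart rate
85 ± 17 vs 81 ± 25, not significant), the ECG-table column averages
(QRS 108 ± 25, QT 480 ± 118, QTc 551 ± 82, HR 82 ± 22, ratio
0.20 ± 0.06), the clinical-table age and dose averages, all 16 printed
QRS/QTc values, and the classifier confusion matrix. The command exits
non-zero if any check fails, so the reproduction doubles as a CI gate.

Evaluate the 0.2 threshold on the case series:

```sh
$ qrsqtc classify --threshold 0.2
{
 "threshold": 0.2,
 "tp": 7,
 "fn": 0,
 "fp": 1,
 "tn": 8,
 "sensitivity": 1.0,
 "specificity": 0.8888888888888888
}
```

All seven VT/VF cases are predicted high-risk; one patient without VT/VF
(ratio 0.17) is a false positive. Audit the reported QTc values against
Bazett recomputation from the printed QT and heart rate:

```sh
$ qrsqtc audit --formula bazett --tol 6 -o audit.csv
5 case(s) flagged: [2, 10, 11, 14, 16]; report in audit.csv
```

The flagged cases are those whose case reports printed a QTc that cannot
be obtained by Bazett from the printed QT/HR pair (the source table mixes
values given in case reports with values recomputed from attached ECGs);
the unflagged cases agree within ~1 ms.

From Python:

```python
from qrsqtc import load_cohort, compare_groups

cohort = load_cohort("packaged")
comp = compare_groups(cohort, "ratio")
print(comp.group_yes.mean, comp.group_no.mean, comp.p_two_tailed)
# 0.15 0.2422... 0.000365...
```

## Caveats

This is a 16-patient case series assembled from published case reports:
the package reproduces its arithmetic exactly, but the 0.2 threshold is
imported rather than derived, and nothing here establishes external
validity. See `docs/methods.md` for the statistical conventions, the
synthetic-data assumptions, and known limitations.
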