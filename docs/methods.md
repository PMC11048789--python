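# Methods

## Problem and data model

`afhrv` discriminates atrial fibrillation (AF) from sinus rhythm (SR) in
60-second windows of RR intervals (times between consecutive R peaks of the
ECG). The input is a beat-annotation stream: beat times, beat-type labels
(normal / atrial / ventricular / artefact / other) and rhythm spans
(SR / AF / other). No waveform processing is done; the pipeline starts from
annotations, as produced by standard Holter analysis software.

## Pre-processing

The RR series of a recording is divided into contiguous 60-s windows on the
record clock. An interval is attributed to the window containing its
*terminating* beat (an RR interval is only realized at its closing R peak);
windows are the half-open intervals `(k·60, (k+1)·60]` s, so an interval
ending exactly on a boundary closes the earlier window.

A window is labelled **SR** only if every interval lies in an SR rhythm span
and terminates in a normal beat; **AF** only if every interval lies in an AF
span and none terminates in a ventricular beat. Anything else is excluded
(`mixed_rhythm`, `ventricular_in_af`, `other_rhythm`, or `other` for an SR
window containing non-normal beats).

Artefact guards: intervals shorter than 240 ms or longer than 3000 ms are
flagged invalid — bounds inclusive, so exactly 240 or 3000 ms is kept.
Invalid intervals are never deleted (the accounting needs them); a window is
discarded when their total duration strictly exceeds 1800 ms (3% of 60 s),
or when the valid intervals total strictly less than 58 000 ms. Retained
windows pass only their valid intervals, concatenated in order, to feature
extraction: one feature vector per window, never sub-windows.

Exclusion accounting is conservative by construction: retained + per-reason
counts = total windows, and this is asserted in tests.

## Features

For a window's valid intervals `RR_1..RR_N` the signed successive
differences are `δ_i = RR_{i+1} − RR_i` (N−1 of them).

**pRRx / pRRx%.** `pRR30` is the percentage of differences with |δ| ≥ 30 ms.
`pRR3.25%` uses a relative threshold, 3.25% of the *previous* interval of
each pair, making it invariant to rescaling the tachogram. Comparisons are
inclusive (≥). The denominator is always N−1.

**Runs-based asymmetric entropy.** Each difference is symbolized by sign:
`+` (deceleration), `−` (acceleration), `0` (neutral). Maximal same-symbol
blocks form deceleration (DR), acceleration (AR) and neutral (NR) runs;
blocks touching the series boundary are counted at their observed length
(dropping them would discard up to two runs per window). Each difference is
assigned the probability of its (run type, length) cell

    p_{i,k} = (# runs of type k with length i) · i / n ,

with `n = N−1` the number of differences, so that Σ p = 1 (taking n as the
number of differences rather than of intervals is what makes the estimator
normalize — runs partition the difference series). The Shannon entropy
(natural log, nats; 0·ln 0 ≡ 0) restricted to one run type gives `HDR`,
`HAR`, `HNR`; `H` is the entropy of the full joint distribution, which
equals `HAR + HDR + HNR` exactly because run types partition the cells (the
identity is asserted to 1e−12, never assumed).

Neutral runs are deliberately retained rather than jittered away with white
noise. On a 128 Hz Holter grid (7.8125 ms resolution) exact zero differences
are common in SR and rare in AF — the irregularly irregular ventricular
response almost never repeats an interval exactly — so the neutral-run
entropy `HNR` itself carries discriminative information.

## Statistical evaluation

AF is the positive class throughout.

* **ROC/AUC** over all distinct thresholds (trapezoid; equal to the pairwise
  Mann–Whitney probability, which the tests verify by enumeration). Each
  score's orientation is auto-chosen so AUC ≥ 0.5 and reported as a
  direction (`af_if_ge` / `af_if_le`); entropies discriminate AF-low,
  pRRx AF-high.
* **Youden cutoff**: the threshold maximizing sensitivity + specificity − 1,
  scanned over midpoints between adjacent distinct observed values plus ±∞;
  ties broken by higher sensitivity, then the smaller threshold.
* **Confusion metrics**: accuracy, sensitivity, specificity, PPV, NPV as
  percentages, and the diagnostic odds ratio DOR = (TP·TN)/(FP·FN) with the
  Haldane–Anscombe +0.5-per-cell correction whenever any cell is zero, so
  DOR stays finite on degenerate tables.
* **Spearman correlations** between features, computed per class (average
  ranks for ties, two-sided p-values; constant columns report NaN).
* **Train/test split** at a 2:1 ratio. Default mode `by_record` keeps every
  recording on one side (no within-subject leakage) and is class-stratified
  over each record's majority class, leaving at least one record per class
  on the test side; `by_segment` is available for comparison. Deterministic
  given the seed; if a side still lacks a class, a validation error asks for
  a reseed.
* **Logistic regression**: unpenalized maximum likelihood on features
  standardized by training mean/SD, AF coded 1. Complete separation —
  routine on cleanly separated synthetic data — is detected from the fitted
  linear score and handled by capping |coefficients| at 30 with a warning;
  the capped score is monotone in the same direction, so ranking metrics are
  unaffected. The default decision threshold for confusion metrics is
  probability 0.5; a Youden cutoff on training probabilities is available
  (`threshold="youden"`).
* **Bootstrap comparison** (B = 1000): the test set is resampled with
  replacement using the *same* indices for every model, so per-resample
  metric differences are paired. 95% CIs are the 2.5th/97.5th percentiles.
  Paired two-sided p-values are `2·min(frac(diff ≤ 0), frac(diff ≥ 0))`,
  floored at 1/B and capped at 1. A resample missing a class is redrawn
  (logged), with a bounded retry rather than an unbounded loop.

## Synthetic tachogram generator

The generator exists so the whole pipeline is exercisable without any data
download. It emulates the *feature-distribution shape* the analysis relies
on, not electrophysiology:

* **SR** (`SRGenParams`): RR_t = mean + AR(1) drift + respiratory sinusoid,
  quantized to the 1/128 s grid. Defaults (versioned in
  `generator_defaults.yaml`): mean 858 ms; AR(1) φ = 0.95 with innovation SD
  6 ms (slow autonomic drift); respiratory amplitude 10 ms at period 6 s
  (~10 breaths/min). The respiratory phase advances with cumulative beat
  time, so the modulation is genuinely periodic in time, not in beat index.
* **AF** (`AFGenParams`): i.i.d. Gaussian RR around 698 ms with SD 110 ms,
  truncated by redraw to (240, 3000) ms, quantized. An optional AR(1)
  `correlation` exists for sensitivity checks; default 0.

Grid quantization is the sole source of neutral symbols. Amplitude choices
follow from that: SR successive differences must frequently round to zero
(|δ| < 3.9 ms) to reproduce the neutral-run-rich SR structure of 128 Hz
Holter data, which is why the respiratory amplitude is 10 ms rather than
larger — at ~25 ms the SR difference magnitudes reach ~30 ms, neutral runs
almost disappear, and the SR/AF entropy ordering inverts. The defaults were
fixed once by a coarse parameter grid against the calibration contract
below (`scripts/calibrate.py`) and are not tuned per experiment.

**Calibration contract** (checked by the script and by tests at fixed
seeds): SR pRR30/pRR3.25% concentrated near 0 with AF modes high; median H
and HNR lower in AF; median HAR and HDR higher in AF; univariate
AUC(pRR3.25%) ≥ 0.95 and ≥ AUC(H).

What the generator does *not* model: ectopy patterns beyond label/artefact
injection, atrial flutter and other confounder rhythms, autonomic
transients, circadian structure, and the heavy overlap of real SR and AF
feature distributions. Synthetic classes separate almost perfectly
(univariate AUCs near 1.0), so passing the end-to-end tests demonstrates
correctness of the machinery and the *direction* of every effect, not the
absolute discriminative performance obtainable on real Holter recordings —
for that, run `afhrv reproduce` on the downloaded database.

`gen_labelled_dataset` groups segments into pure-class pseudo-recordings of
10 so the grouped split is exercisable; `gen_multirhythm_record` produces
whole recordings from a rhythm layout (e.g. SR 90 s then AF 90 s), whose
block boundaries become mixed-rhythm window exclusions downstream.

## Problem sizes

The default test suite and the acceptance script use 500 + 500 synthetic
segments with a 1000-resample bootstrap for the end-to-end study, 1000
random grid-quantized segments for the exact feature-math comparisons, and
200 random instances for the ROC/Youden enumeration checks — sizes at which
every stochastic assertion is stable across reseeds.

## Numerical and degenerate-input policy

* Zero differences are detected by exact comparison; all durations are exact
  binary multiples of the 7.8125 ms grid, so no tolerance is needed.
* Entropy sums use `0·ln 0 ≡ 0`; single-run windows give all-zero entropies.
* Fewer than 2 intervals: feature functions raise a validation error;
  `derive_rr` of a <2-beat stream returns an empty list (not an error).
* Constant features cannot be standardized and are rejected; constant
  columns in correlation matrices report NaN.
* WFDB annotation I/O is a minimal built-in reader/writer for the MIT binary
  annotation dialect (beat codes, `+`/AUX rhythm strings, SKIP intervals,
  header sampling frequency); unknown rhythm strings map to `other` with a
  logged warning.

## Known limitations

* The WFDB reader covers the annotation subset above, not signal files or
  multi-segment records.
* The generator's AF model is i.i.d. by design; real AF retains weak
  short-range correlation.
* Bootstrap p-values are percentile-based and bounded below by 1/B; with
  B = 1000 the smallest reportable p is 0.001.
* `reproduce` assumes one `.atr` + optional `.hea` per recording in a flat
  directory.
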