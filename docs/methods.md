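# Methods

This note documents the models, parameter choices and known limitations of
the `eegarousal` package: what each stage of the pipeline computes, which
defaults matter, what the synthetic data do and do not emulate, and where
the design was genuinely open.

## Preprocessing

EEG channels are band-passed 0.5–70 Hz (4th-order Butterworth) with a 50 Hz
notch of ±2 Hz half-width (IIR notch, Q = f0/4); all filtering is zero-phase
(forward–backward), so stage boundaries are not smeared by filter delay.
EOG channels receive a lower high-pass (0.1 Hz instead of 0.5 Hz): slow eye
movements live below 1 Hz, and a 0.5 Hz high-pass would attenuate the very
feature that separates stage B1 from stage 0.  This is a deliberate
deviation from treating all channels alike.

Recordings are cut into non-overlapping half-open 1-s windows `[t, t+1)`;
a trailing partial second is discarded.  Artifact handling is a
deterministic surrogate for interactive cleaning (ICA plus visual
inspection is out of scope): a segment is rejected when any EEG channel
exceeds a peak amplitude of 100 µV (configurable).  A recording whose
rejected fraction strictly exceeds 15% is excluded; the comparison is made
in exact rational arithmetic, so 135 of 900 segments (exactly 15.0%) is
still usable.  The 15% rule is counted over 1-s segments; whether the
original criterion counted longer stretches is not decidable from the
available description.

Common-average re-referencing subtracts the per-sample mean of the EEG
channels (EOG untouched); staging operates on this reference.

## Vigilance staging

Per 1-s segment, band powers are computed from a Hann-tapered periodogram
at 1 Hz resolution; a band's power is the sum of bins whose center lies in
[lo, hi): delta 2–4, theta 4–7, alpha 8–12, beta 12–25 Hz.  Three regions
of interest (ROIs) — occipital (O1, O2), parietal (P3, P4, Pz), frontal
(F3, F4, Fz) — summarize the alpha topography; the A-substage is the ROI
with maximal mean alpha power (ties resolved occipital > parietal >
frontal), approximating an anterior–posterior center-of-gravity rule with a
small fixed electrode set.

The decision cascade per segment:

1. spindle or K-complex present → **C**;
2. else slow-wave fraction (delta+theta)/total ≥ 0.55 **and** relative
   alpha < 0.40 → **B2/3**;
3. else relative alpha (alpha/total in the maximal ROI) ≥ 0.40 → **A1/A2/A3**
   by ROI;
4. else slow eye movement present → **B1**;
5. else → **0**.

Relative (not absolute) power thresholds make the spectral decisions
amplitude-scale invariant; subject-adaptive absolute thresholds are a known
alternative used by interactive staging tools and could be substituted via
`ClassifierConfig`.  All event detectors use absolute amplitudes:

* **SEM**: the horizontal-EOG derivation (left canthus − right canthus) is
  smoothed by a moving-average cascade (0.25 s and 0.35 s windows,
  suppressing blinks/saccades/EMG above ~1 Hz) and detrended by a 4-s
  moving average — together isolating roughly the 0.1–1 Hz band while
  remaining well-behaved on short snippets, where a narrow zero-phase IIR
  band-pass rings for longer than the data.  A monotone deflection
  ≥ 25 µV lasting ≥ 0.5 s that overlaps the segment marks a SEM.  Without
  any horizontal EOG the classifier runs degraded: B1 collapses into 0 and
  a warning is logged.
* **Spindles**: 11–16 Hz amplitude envelope (Hilbert) of the fronto-central
  channel mean exceeding 3× the subject's median envelope — with an
  absolute floor of 10 µV so that sustained low-voltage beta cannot
  masquerade as spindle activity — for ≥ 0.5 s.
* **K-complexes**: on the 0.5–6 Hz band, two consecutive extrema with
  peak-to-peak ≥ 100 µV completing within 0.25–1.5 s.

These numeric thresholds are this package's own calibration: the staging
literature defers to tool manuals that are not reproduced here, so the
defaults were chosen once such that the bundled synthetic generator
round-trips at ≥ 90% per-segment agreement, and all are exposed in
`ClassifierConfig`.  The merged stage B2/3 is kept merged.

## Arousal stability score

The score condenses the stage sequence into one integer (1–11) over three
5-minute blocks (segment indices [0,300), [300,600), [600,900) by original
timing; shorter recordings use the blocks they reach).  Criteria are
evaluated lowest score first, first match wins: C in block 1/2/3 → 1/2/3;
B2/3 fraction ≥ 1/3 in block 1/2/3 → 4/5/6; B1 fraction ≥ 1/3 → 7/8/9;
else ≥ 2/3 of all segments in {0, A1} → 11; ≥ 2/3 in {0, A1, A2, A3} → 10.
The ascending order makes deep decline dominate (a single sleep-onset
segment outranks any amount of wake), which is the only ordering consistent
with the published group examples.  Two open points are resolved as
explicit, configurable choices: (a) when no criterion fires (possible with
scattered sub-threshold B stages) the fallback score is 10 — absence of any
sustained decline evidence is the non-hypoaroused regime — and the result
carries a `fallback_used` flag; (b) artifact segments are excluded from
both numerators and denominators.  Fractions compare as exact rationals
(`Fraction`), so the ≥ 1/3 and ≥ 2/3 boundaries are decided without
floating-point ambiguity.  Scores ≤ 6 → hypoaroused, ≥ 7 → non-hypoaroused.

## Questionnaires

MFI-20: five 4-item dimensions, each 4–20; positively-worded items are
recoded 6 − value.  The item→dimension key and reversal set follow the
published instrument structure and are config data.  BDI-II: 21 items 0–3
(items 16/18 accept the seven-option tokens 0, 1a…3b, collapsed to 0–3),
total 0–63.  ESS: 8 items 0–3, total 0–24, with a strict >10 flag for
excessive daytime sleepiness.  SSS: one 1–7 rating.  SF-A/R: sleep quality
as the mean of its 1–5 items (exact factor weights are not published; the
mean is a documented approximation) and total time in bed from bed/rise
clock times with midnight wrap.

A questionnaire with more than 2 missing items excludes the subject.  Up to
2 missing items are imputed with the rounded person-mean of the answered
items of the same scale (same dimension for the MFI) — the admissibility
rule is given by the study design, the imputation is this package's
deterministic choice of standard practice.  Inclusion requires the general
fatigue dimension to strictly exceed the sex- and age-band 75th-percentile
population norm.  The German population norm table is published reference
data not reproduced here; `synthetic_norm_table()` ships a clearly-labelled
synthetic placeholder (constant p75 = 12, three age bands 18–39 / 40–59 /
60+) and real norms must be supplied via CSV for substantive use.

## Statistics

* **Mann–Whitney U**: Z = (U₁ − n₁n₂/2)/σ with tie-corrected σ and no
  continuity correction, matching the asymptotic Z that standard clinical
  statistics packages print; p two-sided from the normal law.  Sign
  convention: Z < 0 when the first-listed (non-hypoaroused) group has the
  lower mean rank.  The uncorrected asymptotic p estimates the *mid-p* of
  the exact permutation distribution; for group sizes ≥ 4 they agree within
  0.03 (verified by full enumeration in the tests), while for smaller
  groups no normal approximation is adequate under any convention.
* **η² = Z²/N** (configurable alternative Z²/(N−1)); reported with a
  percentile-bootstrap 90% CI over 10,000 replications, groups resampled
  independently with replacement at their observed sizes, deterministic
  under the seed.  The percentile method (not BCa) is used; percentile
  intervals of a non-negative statistic need not contain the point estimate
  symmetrically, and no such property is asserted.
* **χ²**: Pearson, df = 1, no continuity correction; all margins must be
  positive.
* **Partial Spearman**: all variables rank-transformed (average ranks),
  x and y residualized on the covariates by least squares with intercept,
  Pearson correlation of residuals, p from t with n − 2 − k df.  Collinear
  covariates are rejected with the offending column named.

No multiple-testing correction is applied, mirroring the analysis plan the
package reproduces.

## Synthetic data

**EEG.**  Stage scripts (`stable_high`, `declining`, `fluctuating`,
`custom`) define a ground-truth per-second trajectory whose true stability
score is computed at construction.  The signal generator emits, per stage
run with phase continuity: desynchronized beta (five components 16.5–24.5
Hz, ~8 µV RMS total) for stages 0/B1; a 10 Hz alpha oscillation with a 2:1
amplitude gradient favouring the stage's ROI (30 µV dominant) for A-stages;
0.25 Hz, ±30 µV antiphase slow eye movements on the canthus EOG channels
for B1; delta (3 Hz, 28 µV) plus theta (5.5 Hz, 20 µV) for B2/3; and for C
seconds the B2/3 background plus alternating 13 Hz 0.8-s spindle bursts
(25 µV, flat-topped) and ~140 µV peak-to-peak biphasic K-complexes on an
attenuated background.  Background oscillations are spatially *incoherent*
(independent phase per channel), as desynchronized cortical activity is —
this also means common-average referencing preserves their power — while
transients use a zero-mean dipolar fronto-central topography that the
common average leaves intact.  Pink 1/f noise (3 µV RMS) underlies
everything.  Default sampling rate 256 Hz keeps full 15-min recordings fast
to synthesize and classify; the study-grade 1 kHz is supported.

What this does *not* emulate: volume-conducted artifact topographies, real
spindle/K-complex morphology variability, alpha slowing, medication
effects, or any head-model geometry.  Passing round-trip tests therefore
show internal consistency of generator and classifier under the stated
spectral definitions — not clinical validity on real EEG.

**Cohorts.**  Questionnaire scale totals are drawn per group from truncated
normal distributions at the configured group means/SDs (defaults: the
study's group tables, e.g. trait sleepiness 8.3 ± 4.0 vs 10.4 ± 4.0, group
sizes 78/24, age/sex margins 61 F / 41 M).  The location parameter is
moment-matched so the *truncated* mean equals the configured mean
(truncation at scale bounds would otherwise bias totals by a few
hundredths of an SD).  Item vectors are back-filled deterministically from
each total (evenly spread, MFI reversal undone so scoring recovers the
target); inter-item correlation structure is deliberately not modelled —
sufficient for exercising scoring and statistics, documented as a
limitation.  Categorical variables (sex, medication, suicide-attempt
history, diagnosis code, family history) are Bernoulli draws at the
group-specific published margins.

## Numerical choices and degenerate inputs

Exact rational comparison at all scoring boundaries; strict inequalities
where the source text says "exceeding"/"over" (inclusion cut-off, ESS > 10,
artifact fraction > 15%).  Identical samples in the Mann–Whitney test yield
Z = 0, p = 1 (logged, not an error).  Missing horizontal EOG degrades
staging (B1→0) instead of failing.  Per-subject errors in a batch are
quarantined with machine-readable reasons; only an empty final cohort
aborts a run.  All stochastic components take explicit seeds and are
reproducible bit-exact.

## Problem sizes used in validation

The bundled validation runs classify fifty 15-min recordings at 256 Hz on a
9-channel ROI-covering montage for the calibration contract (≥ 80% exact
score recovery, never off by more than 1), compare the stability scorer
against an independent brute-force evaluator on 10,000 random sequences,
enumerate the full Mann–Whitney permutation distribution for all group
sizes up to 8, and simulate 1,000 null cohorts for the type-I-error check.
These sizes were chosen so the whole suite validates every claim at
desk scale.
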