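# Methods

This note documents the models, algorithms and numerical choices behind
`afscreen`, in the spirit of a methods appendix: what is simulated, how
each stage works, which parameters matter, and what the synthetic
experiments do and do not demonstrate.

## Synthetic single-lead ECG model

Each record is 15 s of one lead-II-like channel sampled at 500 Hz
(configurable; 500 Hz is a standard diagnostic-quality rate that resolves
P waves; handheld recorders rarely publish their internal rate). A record
is built in three layers.

**Beat schedule.** RR intervals are drawn i.i.d. per rhythm class and
truncated to the physiologic range [0.3, 2.0] s:

* sinus, junctional, paced: normal with class-default coefficients of
  variation 0.03 / 0.02 / 0.005 around 60/HR — low-variability rhythms;
* AF: Gamma with shape 1/CV², CV = 0.24 — the irregularly-irregular
  pattern. CV ≈ 0.24 sits in the range reported for AF RR series and is
  comfortably separated from sinus variability on 15 s windows;
* ectopy (APC/VPC): `round(ectopy_rate)` normal intervals are replaced by
  a premature coupling interval (0.55 of the local RR) followed by a
  pause — non-compensatory (0.95 of the mean RR, a sinus-node reset) for
  APCs, fully compensatory (2·RR − coupling) for VPCs. Ectopic beats are
  labelled in the record truth.

The first beat sits at 0.4 s and the schedule stops one interval short of
the record end so every wave fits; drawing is deterministic given the seed.

**Waveforms.** Each beat is a sum of Gaussians (P, Q, R, S, T). Template
shares are chosen so the rendered QRS peak-to-trough equals the nominal
`qrs_amplitude` within a few percent. AF and junctional rhythms suppress
the P wave; AF additionally renders continuous fibrillatory waves — an
amplitude- and phase-modulated sinusoid at 6 Hz (≈360/min), default
0.08 mV. VPC beats are wide, large and with discordant T; paced beats
carry a 2 ms pacing spike 45 ms before the QRS. A low-voltage morphology
(`qrs_amplitude` < 0.5 mV) is expressible because low QRS voltage is a
documented driver of screening false positives.

**Artifacts.** Additive, with truth bookkeeping: sinusoidal baseline
wander (sub-0.5 Hz), white broadband noise, and one contiguous burst of
strong noise covering exactly `corrupted_fraction` of the duration at a
random position. A zero-noise spec is the identity.

**Cohorts.** Subjects get an age from a clipped normal (58.1 ± 15.0 y,
bounds 20–95), sex (36.6% male), and AF status from age-stratum
prevalences (0.8% for ≤65 y, 4.2% for >65 y — community screening
figures). Non-AF subjects draw a rhythm from a community mix dominated by
plain sinus (96%) with small APC/VPC/junctional/paced fractions; 3/22 of
AF records also carry VPCs. Each record receives a target quality class
with probabilities 83.5 / 12.8 / 2.7 / 0.8 / 0.2 % for grades
0/1/2a/2b/3, mapped to noise parameters (grade 0 nearly clean up to
grade 3 fully corrupted). About 4% of subjects contribute a second
recording, so per-ECG and per-subject denominators differ as they do in
real screening. Everything derives from one master seed via sequential
draws; manifests are byte-identical across runs.

*What the generator does not emulate:* real electrode-motion transients,
muscle-artifact spectra, respiration-modulated morphology, drift in
electrode impedance, atrial flutter, and the continuum of borderline
physician judgments. Passing the synthetic experiments therefore shows the
chain is correct and well-behaved under the stated signal model — not that
its operating point transfers to any particular device population.

## Baseline removal

A linear-phase FIR high-pass designed with `scipy.signal.firwin`:
cutoff 0.67 Hz (the classic diagnostic-ECG baseline bound), Hamming
window, tap count = 3 s × fs rounded to odd (1501 at 500 Hz). The tap sum
is forced to zero (a symmetric per-tap shift of ~10⁻⁶) so a constant
offset is rejected exactly. Because the filter is exactly linear-phase,
it is applied as a single FFT convolution with the integer group delay
compensated and reflect-padded ends — zero phase, so R-peak times do not
move. The single-pass magnitude response leaves ≤ 0.054 of a 0.3 Hz
wander and passes 10 Hz content at 1.000.

## Feature extraction

**QRS detection** follows the Pan-Tompkins recipe: 5–25 Hz zero-phase
band-pass, derivative, squaring, 120 ms moving-window integration,
candidate peaks ≥ 200 ms apart, threshold at 0.2 × the 90th-percentile
candidate height (beat energies are mutually comparable, so a quantile
threshold adapts to amplitude without tracking state), refinement to the
largest absolute band-passed excursion within ±100 ms, refractory
re-enforcement. Samples inside artifact-flagged windows are zeroed first
so noise bursts cannot masquerade as beats; an empty result is valid and
marks the record ungradable.

**RR statistics** on intervals between usable consecutive peaks (peaks in
flagged windows, and intervals spanning a flagged window, are dropped):
CV = sample SD (n−1)/mean, RMSSD/mean, and the fraction of successive
differences > 50 ms (the pNN50 convention). At least 3 intervals are
required; otherwise the record cannot be auto-classified.

**P-wave score** operationalizes "discernible, distinct P waves". For
each beat the window [R−250, R−80] ms is searched, with the window start
clipped to 360 ms after the previous R so the preceding T wave stays out
(windows shorter than 60 ms, off-record or touching artifact-masked
samples are skipped). The window is smoothed with a 20 ms boxcar — a P
wave is a 60–120 ms bump, so smoothing suppresses broadband spikes without
touching it. A beat is P-positive when the dominant positive deflection
(a) exceeds max(0.05 mV, 2× the robust local noise SD), (b) has a crest
factor ≥ 1.9 (a Gaussian bump scores ≈ 2, a sinusoidal f-wave only √2 —
measured crest distributions separate at ≈ 1.95), and (c) peaks within
30 ms of the median P offset across beats (random f-wave or noise maxima
have no stable latency). The score is the fraction of evaluated beats
passing all three; it is deterministic and non-decreasing in the true P
amplitude.

**QRS voltage** is the median peak-to-trough within ±60 ms of each peak.

## Quality grading

"Artifact percentage" is the time fraction of flagged 1 s windows; a
window is flagged by majority vote over 0.25 s sub-windows whose >40 Hz
RMS exceeds 0.15 mV (QRS energy lives below ~40 Hz) or which clip beyond
3 mV. The sub-window vote keeps the measured fraction within one window
of a burst's true extent even when the burst straddles window boundaries.
Baseline-wander severity is the RMS of sub-0.5 Hz content after
filtering: none < 0.05 mV ≤ mild < 0.2 mV ≤ significant.

The grade mapping, evaluated in order: no usable QRS → **3**; fraction
≤ 5% and no wander → **0**; fraction < 33% with recognizable P (score
≥ 0.5) and no significant wander → **1**; fraction ≤ 66% (or mild wander)
with recognizable P and no significant wander → **2a**; otherwise → **2b**.
The 33/66% bands follow the printed inequalities with 66% itself in the
2a band. Grading is deterministic and monotone in the artifact fraction.
One known quirk is inherent to making a physician scale computable: an AF
record with moderate noise has no P waves to "recognize" and can grade 2b
where a physician would reason about f-waves; such records remain
gradable and classified, so the effect on evaluation is nil.

## AF decision and calibration

`AF ⇔ (rr_cv ≥ τ_cv ∨ rmssd/mean ≥ τ_rmssd) ∧ (p_score < τ_p)`, with
grade-3 or feature-poor records UNGRADABLE. Defaults τ_cv = 0.12,
τ_rmssd = 0.10, τ_p = 0.5 are conventional AF-detector operating points.
`calibrate_thresholds` grid-searches τ_cv, τ_rmssd ∈ {0.05…0.30 step
0.01}, τ_p ∈ {0.3…0.7 step 0.1} maximizing Youden's J on a labelled
cohort. Because the synthetic classes separate well, many grid points tie
at the optimum; the most central tied combination (marginal medians,
snapped to the nearest tied grid point, lexicographic final tie-break) is
returned instead of a corner, which generalizes far better to held-out
cohorts while staying fully deterministic. Calibration refuses
single-class cohorts. APC/VPC detection is intentionally absent from the
output: the decision is binary, and the conjunction with P-absence is
what suppresses ectopy-driven false positives (assertable against the
RR-only variant via `decide_table(..., rr_only=True)`).

## Evaluation

Confusion tables per age stratum (≤65 / >65 / overall) after removing
excluded grades and UNGRADABLE calls. Rates are reported in percent to
1 decimal, round-half-up; zero-denominator rates are reported as missing
rather than raised. Sensitivity and specificity carry exact
Clopper-Pearson intervals from beta quantiles (lower bound 0 at zero
successes, upper 100 at full successes), validated in the tests against a
brute-force bisection on exact binomial tails. PPV and NPV carry
logit/delta-method intervals whose variance combines the binomial
variances of sensitivity and specificity — the appropriate interval for
predictive values, and the one that matches every printed predictive-value
CI in the study table this package reconstructs; at a degenerate point
estimate (0 or 1) the logit interval is undefined and the bare point is
reported, as the published table itself does.

The study reconstruction takes the printed counts (965 gradable ECGs, 22
reference-AF, 1 false negative, 22 false positives; strata 526/439 with
4/18 reference-AF; per-subject denominators 496/426/922) as inputs,
recovers the unprinted stratum false positives by inverting the printed
stratum PPVs (4 TP at 36.4% → 7 FP; 17 TP at 53.1% → 15 FP), and
verifies both that they sum to the printed overall 22 and that the
stratum tables add cell-wise to the overall table before reporting.

## Problem sizes and determinism

The end-to-end synthetic experiment uses 500-subject cohorts (~515 ECGs
with repeats, ~10 AF records at community prevalence) — large enough for
stable stratified tables while a full calibrate-plus-evaluate run stays
under a minute on one core. Unit fixtures use single records or
120-subject cohorts. Every random draw flows from an explicit integer
seed through `numpy.random.default_rng`; no stage reads the clock or any
global RNG, so identical seeds give byte-identical manifests, features
and reports.

## Limitations

* The synthetic signal model is parametric and clean by construction;
  real-device noise, flutter, and borderline morphologies are out of scope.
* The quality scale emulates a physician judgment with fixed thresholds;
  agreement with the injected grade classes is verified coarsely
  (grade 0/1 vs 2 vs 3), not per subclass.
* The P-wave score is tuned to lead-II-like morphology with positive P
  waves; inverted or biphasic P waves would need a signed extension.
* An SVM decision branch is not implemented; the classifier accepts only
  the rule-based path, though `decide_table` isolates the decision so an
  alternative model can be slotted in.
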