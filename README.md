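# afscreen

Community screening for atrial fibrillation (AF) increasingly relies on
short single-lead ECG recordings read automatically by an algorithm and
over-read by a physician. `afscreen` is a self-contained Python
implementation of that screening computation for 15-second single-lead
tracings, built for people who study or audit such algorithms: it
generates fully ground-truthed synthetic screening cohorts, runs the
detection chain, and evaluates it exactly the way screening studies report
their results.

The package covers six stages:

1. **Synthetic ECG cohorts** — 15 s lead-II-like tracings (sum-of-Gaussians
   beat morphology) for sinus rhythm, sinus with atrial/ventricular
   premature complexes (APC/VPC), AF (Gamma-distributed irregular RR,
   fibrillatory f-waves instead of P waves), junctional and paced rhythms;
   age-stratified AF prevalence; injectable baseline wander, broadband
   noise and burst corruption with per-record truth.
2. **Baseline removal** — linear-phase FIR high-pass (0.67 Hz, Hamming,
   ~3 s of taps) applied zero-phase.
3. **Feature extraction** — Pan-Tompkins-style QRS detection; RR
   irregularity statistics (CV, RMSSD/mean, pNN50); a P-wave presence
   score; QRS voltage.
4. **Quality grading** — the five-level artifact scale 0 / 1 / 2a / 2b / 3
   (artifact percentage with 33%/66% bands, P/QRS recognizability,
   baseline-wander severity); grade 3 is excluded from evaluation.
5. **AF decision** — the rule an over-reading cardiologist applies:
   positive iff RR intervals are irregular **and** no distinct P waves are
   present. Thresholds can be calibrated by maximizing Youden's J on a
   labelled cohort.
6. **Evaluation** — sensitivity / specificity / PPV / NPV per age stratum
   (≤65 / >65 / overall) with exact Clopper-Pearson CIs for the binomial
   rates and logit CIs for the predictive values, plus prevalence by ECG
   and by screened subject.

The decision rule is deliberately a conjunction: RR irregularity alone
flags most ectopy (APC/VPC with preserved P waves), which is the dominant
false-positive mode of RR-only detectors. With sensitivity `Se`,
specificity `Sp` and prevalence `π`, the reported predictive values obey

    PPV = Se·π / (Se·π + (1 − Sp)(1 − π)),   NPV = Sp(1 − π) / ((1 − Se)π + Sp(1 − π))

and the package asserts this Bayes consistency for every stratum it reports.

## Worked example

```python
from afscreen import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=11, n_subjects=150))
print(result.rendered)
```

prints (tab-separated):

```
Result of screening algorithm  Age <=65 years (n=108)      Age >65 years (n=48)       Overall (n=156)
Sensitivity, % (95% CI)        100.0 (95% CI 15.8%-100.0%) 100.0 (95% CI 2.5%-100.0%) 100.0 (95% CI 29.2%-100.0%)
Specificity, % (95% CI)        100.0 (95% CI 96.6%-100.0%) 100.0 (95% CI 92.5%-100.0%) 100.0 (95% CI 97.6%-100.0%)
Positive predictive value, % (95% CI)  100.0  100.0  100.0
Negative predictive value, % (95% CI)  100.0  100.0  100.0
Disease prevalence (by ECG numbers), % (n/N)      1.9 (2/108)  2.1 (1/48)  1.9 (3/156)
Disease prevalence (by screening resident numbers), % (n/N)  1.9 (2/104)  2.2 (1/46)  2.0 (3/150)
```

This 150-subject cohort contains 3 AF recordings (one subject older than
65, two younger); the pipeline finds all 3 with no false positives, so
every rate is 100% — the wide sensitivity CIs (e.g. 2.5%–100.0% for the
single elderly case) are what exact binomial intervals look like at tiny
positive counts. At 500 subjects the cohort carries ~10 AF records and a
realistic grade mix, and false positives start to appear once the
P-absence requirement is dropped (`decide_table(..., rr_only=True)`).

The same stages are available from the shell:

```
afscreen simulate --out cohort/ --seed 3 --n-subjects 50
afscreen preprocess --in cohort/records/R00000.csv --out filtered.csv
afscreen run-all --out run/ --seed 7
afscreen reconstruct-table1
```

`afscreen reconstruct-table1` rebuilds, from the printed counts of a
published community screening study (965 gradable ECGs, 22 physician-read
AF, 1 false negative, 22 false positives), its full age-stratified
performance table — overall sensitivity 95.5% (95% CI 77.2%–99.9%),
specificity 97.7% (96.5%–98.5%), PPV 48.8% (38.5%–59.3%), NPV 99.9%
(99.3%–100.0%) — including the stratum false positives that were never
printed, recovered from the stratum PPVs.

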