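"""Generator contracts: RR schedules, waveform rendering, artifacts, cohorts."""

import numpy as np
import pytest
from scipy import signal as sps

from afscreen.errors import InvalidParameterError
from afscreen.features import P_WINDOW, T_CLEARANCE
from afscreen.synthetic import (CohortSpec, NoiseSpec, RhythmClass, RhythmSpec,
                                WaveformParams, add_artifacts, generate_cohort,
                                generate_record, generate_rr_sequence,
                                synthesize_ecg)


class TestRRSequence:
    def test_sinus_60bpm_count_and_cv(self):
        r, types = generate_rr_sequence(RhythmSpec(mean_hr=60, rr_cv=0.03, seed=1))
        rr = np.diff(r)
        assert 14 <= rr.size <= 16
        assert np.std(rr, ddof=1) / np.mean(rr) <= 0.05
        assert np.all(types == "N")

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_af_is_irregular(self, seed):
        spec = RhythmSpec(rhythm_class=RhythmClass.AF, mean_hr=90, seed=seed)
        r, _ = generate_rr_sequence(spec)
        rr = np.diff(r)
        assert np.std(rr, ddof=1) / np.mean(rr) >= 0.15

    def test_af_more_irregular_than_sinus_at_same_rate(self):
        for seed in range(3):
            af, _ = generate_rr_sequence(
                RhythmSpec(rhythm_class=RhythmClass.AF, mean_hr=80, seed=seed))
            si, _ = generate_rr_sequence(
                RhythmSpec(rhythm_class=RhythmClass.SINUS, mean_hr=80, seed=seed))
            cv = lambda r: np.std(np.diff(r), ddof=1) / np.mean(np.diff(r))
            assert cv(af) > cv(si)

    def test_schedule_fills_duration(self):
        r, _ = generate_rr_sequence(RhythmSpec(mean_hr=75, seed=5), duration=15)
        rr = np.diff(r)
        assert r[-1] >= 15 - rr.max() - 0.5  # no large unexplained gap at the end

    def test_invalid_duration_raises(self):
        with pytest.raises(InvalidParameterError):
            generate_rr_sequence(RhythmSpec(mean_hr=60), duration=0)

    def test_invalid_hr_raises(self):
        with pytest.raises(InvalidParameterError):
            RhythmSpec(mean_hr=10)

    @pytest.mark.parametrize("rhythm", [RhythmClass.SINUS_APC, RhythmClass.SINUS_VPC])
    def test_ectopy_count_matches_truth(self, rhythm, make_record):
        rec = make_record(rhythm, seed=42, ectopy_rate=3.0)
        assert rec.truth.n_ectopic == 3

    def test_no_ectopy_in_plain_sinus(self, sinus_record):
        assert sinus_record.truth.n_ectopic == 0

    def test_determinism(self):
        spec = RhythmSpec(rhythm_class=RhythmClass.AF, mean_hr=95, seed=99)
        a, _ = generate_rr_sequence(spec)
        b, _ = generate_rr_sequence(spec)
        assert np.array_equal(a, b)


class TestSynthesize:
    @pytest.mark.parametrize("fs,duration", [(500, 15), (250, 15), (500, 10)])
    def test_sample_count(self, fs, duration, wf):
        spec = RhythmSpec(mean_hr=70, seed=3)
        r, types = generate_rr_sequence(spec, duration)
        rec = synthesize_ecg(r, types, wf, fs=fs, duration=duration)
        assert rec.samples.size == round(fs * duration)

    def test_truth_peaks_match_schedule(self, sinus_record):
        r = sinus_record.truth.r_peaks
        assert np.all(np.diff(r) > 0)
        # beats sit where the RR schedule places them
        assert sinus_record.samples.size == 7500

    def test_low_fs_raises(self, wf):
        r, types = generate_rr_sequence(RhythmSpec(mean_hr=70, seed=3))
        with pytest.raises(InvalidParameterError):
            synthesize_ecg(r, types, wf, fs=50)

    def test_low_voltage_mode(self, make_record):
        rec = make_record(RhythmClass.SINUS, seed=1,
                          wf_override=WaveformParams(qrs_amplitude=0.4))
        assert rec.samples.max() < 0.5

    def test_af_has_no_p_waves_only_f_waves(self, af_record, wf):
        """Pre-R windows of AF contain only f-waves (bounded amplitude)."""
        x, fs = af_record.samples, af_record.fs
        peaks = af_record.truth.r_peaks
        checked = 0
        for k, r in enumerate(peaks):
            start = r + P_WINDOW[0]
            if k > 0:
                start = max(start, peaks[k - 1] + T_CLEARANCE)
            if (r + P_WINDOW[1]) - start < 0.06:
                continue
            w = x[int(start * fs):int((r + P_WINDOW[1]) * fs)]
            # AM modulation peaks at 1.3x the nominal f-wave amplitude
            assert np.mean(np.abs(w)) <= 1.3 * wf.f_wave_amplitude
            checked += 1
        assert checked >= 3


class TestArtifacts:
    def test_zero_noise_is_identity(self, sinus_record):
        out = add_artifacts(sinus_record, NoiseSpec())
        assert np.array_equal(out.samples, sinus_record.samples)

    def test_corrupted_fraction_truth(self, sinus_record):
        out = add_artifacts(sinus_record, NoiseSpec(corrupted_fraction=0.5, seed=4))
        total = sum(t1 - t0 for t0, t1 in out.truth.corrupted_intervals)
        assert abs(total - 7.5) <= 1.0

    def test_wander_spectral_peak(self, sinus_record):
        noise = NoiseSpec(baseline_wander_amplitude=1.0, baseline_wander_freq=0.3, seed=4)
        out = add_artifacts(sinus_record, noise)
        diff = out.samples - sinus_record.samples
        f, p = sps.periodogram(diff, fs=sinus_record.fs)
        assert abs(f[np.argmax(p)] - 0.3) < 0.1


class TestCohort:
    def test_stratum_prevalence_within_binomial_bounds(self, small_cohort):
        from scipy.stats import binom
        _, manifest = small_cohort
        sub = manifest.drop_duplicates("subject_id")
        for hi, prev in ((False, 0.008), (True, 0.042)):
            grp = sub[(sub.age > 65) == hi]
            n = len(grp)
            af = grp["true_rhythm"].isin(["AF", "AF_VPC"]).sum()
            lo, up = binom.ppf(0.025, n, prev), binom.ppf(0.975, n, prev)
            assert lo <= af <= up

    def test_manifest_determinism(self):
        spec = CohortSpec(n_subjects=40, seed=123)
        _, m1 = generate_cohort(spec)
        _, m2 = generate_cohort(spec)
        assert m1.to_csv(index=False) == m2.to_csv(index=False)

    def test_record_determinism(self):
        spec = CohortSpec(n_subjects=10, seed=5)
        r1, _ = generate_cohort(spec)
        r2, _ = generate_cohort(spec)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.samples, b.samples)

    def test_degenerate_mix_has_no_af(self):
        spec = CohortSpec(n_subjects=50, seed=2, prevalence_le65=0.0,
                          prevalence_gt65=0.0, non_af_mix={RhythmClass.SINUS: 1.0})
        _, manifest = generate_cohort(spec)
        assert set(manifest["true_rhythm"]) == {"SINUS"}

    def test_invalid_n_raises(self):
        with pytest.raises(InvalidParameterError):
            CohortSpec(n_subjects=0)

    def test_manifest_columns(self, small_cohort):
        _, manifest = small_cohort
        assert {"record_id", "subject_id", "age", "sex", "true_rhythm",
                "grade_class", "seed"} <= set(manifest.columns)
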