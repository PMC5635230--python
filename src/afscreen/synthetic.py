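"""Synthetic single-lead ECG generator.

Produces 15-second lead-II-like tracings with known rhythm, morphology and
artifact ground truth, so the whole screening chain (filtering, feature
extraction, quality grading, AF classification, evaluation) is testable
without any real recordings.

Rhythm classes cover what a community screening cohort actually contains:
sinus rhythm with or without atrial/ventricular premature complexes (APC /
VPC), atrial fibrillation (irregularly irregular RR, no P waves, continuous
fibrillatory f-waves), junctional rhythm (regular, absent P) and paced
rhythm (regular, pacing spike before the QRS).  Beat morphology is a
sum-of-Gaussians template per wave (P, Q, R, S, T) — the standard fully
parametric approach for synthetic ECGs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .records import ECGRecord, RecordTruth

__all__ = [
    "RhythmClass",
    "RhythmSpec",
    "WaveformParams",
    "NoiseSpec",
    "CohortSpec",
    "generate_rr_sequence",
    "synthesize_ecg",
    "add_artifacts",
    "generate_cohort",
    "generate_record",
]


class RhythmClass(str, enum.Enum):
    SINUS = "SINUS"
    SINUS_APC = "SINUS_APC"
    SINUS_VPC = "SINUS_VPC"
    SINUS_APC_VPC = "SINUS_APC_VPC"
    AF = "AF"
    AF_VPC = "AF_VPC"
    JUNCTIONAL = "JUNCTIONAL"
    PACED = "PACED"

    @property
    def is_af(self) -> bool:
        return self in (RhythmClass.AF, RhythmClass.AF_VPC)

    @property
    def has_p_waves(self) -> bool:
        """Whether the underlying rhythm produces sinus P waves."""
        return self in (
            RhythmClass.SINUS,
            RhythmClass.SINUS_APC,
            RhythmClass.SINUS_VPC,
            RhythmClass.SINUS_APC_VPC,
        )

    @property
    def ectopic_type(self) -> str | None:
        if self in (RhythmClass.SINUS_APC, RhythmClass.SINUS_APC_VPC):
            return "A"
        if self in (RhythmClass.SINUS_VPC, RhythmClass.AF_VPC, RhythmClass.SINUS_APC_VPC):
            return "V"
        return None


#: default RR coefficient of variation per rhythm class (dimensionless)
DEFAULT_RR_CV = {
    RhythmClass.SINUS: 0.03,
    RhythmClass.SINUS_APC: 0.03,
    RhythmClass.SINUS_VPC: 0.03,
    RhythmClass.SINUS_APC_VPC: 0.03,
    RhythmClass.AF: 0.24,
    RhythmClass.AF_VPC: 0.24,
    RhythmClass.JUNCTIONAL: 0.02,
    RhythmClass.PACED: 0.005,
}

#: physiologic truncation bounds for any RR interval (s)
RR_BOUNDS = (0.3, 2.0)

#: time of the first beat after record start (s); leaves room to render P and QRS
FIRST_BEAT_OFFSET = 0.4

#: margin kept free at the end of the record so the last T wave fits (s)
END_MARGIN = 0.05


@dataclass
class RhythmSpec:
    """Rhythm-level generator parameters for one record."""

    rhythm_class: RhythmClass = RhythmClass.SINUS
    mean_hr: float = 70.0  # beats/min
    rr_cv: float | None = None  # None -> class default
    ectopy_rate: float = 0.0  # ectopic beats per recording
    seed: int = 0

    def __post_init__(self) -> None:
        self.rhythm_class = RhythmClass(self.rhythm_class)
        if not (30.0 <= self.mean_hr <= 220.0):
            raise InvalidParameterError(f"mean_hr must be in [30, 220], got {self.mean_hr}")
        if self.rr_cv is not None and self.rr_cv < 0:
            raise InvalidParameterError("rr_cv must be >= 0")
        if self.ectopy_rate < 0:
            raise InvalidParameterError("ectopy_rate must be >= 0")

    @property
    def effective_rr_cv(self) -> float:
        return DEFAULT_RR_CV[self.rhythm_class] if self.rr_cv is None else self.rr_cv


@dataclass
class WaveformParams:
    """Per-beat wave morphology (amplitudes in mV, widths as Gaussian sigma in s)."""

    p_amplitude: float = 0.15
    qrs_amplitude: float = 1.0  # rendered peak-to-trough of the QRS complex
    t_amplitude: float = 0.25
    p_width: float = 0.022
    qrs_width: float = 0.009
    t_width: float = 0.05
    f_wave_amplitude: float = 0.08  # AF fibrillatory waves
    f_wave_freq: float = 6.0  # Hz, typical coarse f-wave rate ~350/min

    def __post_init__(self) -> None:
        for name in ("p_amplitude", "qrs_amplitude", "t_amplitude", "f_wave_amplitude"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        for name in ("p_width", "qrs_width", "t_width"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.f_wave_freq <= 0:
            raise InvalidParameterError("f_wave_freq must be > 0")


@dataclass
class NoiseSpec:
    """Additive artifact model: baseline wander, broadband noise, burst corruption."""

    baseline_wander_amplitude: float = 0.0  # mV
    baseline_wander_freq: float = 0.3  # Hz, must stay sub-0.5 Hz
    broadband_noise_sd: float = 0.0  # mV
    corrupted_fraction: float = 0.0  # fraction of the recording under burst noise
    burst_noise_sd: float = 1.2  # mV, noise level inside corrupted stretches
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.corrupted_fraction <= 1.0):
            raise InvalidParameterError("corrupted_fraction must be in [0, 1]")
        for name in ("baseline_wander_amplitude", "broadband_noise_sd", "burst_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not (0.0 < self.baseline_wander_freq < 0.5):
            raise InvalidParameterError("baseline_wander_freq must be in (0, 0.5) Hz")

    @property
    def is_identity(self) -> bool:
        return (
            self.baseline_wander_amplitude == 0.0
            and self.broadband_noise_sd == 0.0
            and self.corrupted_fraction == 0.0
        )


#: rhythm mix of a community screening population, conditional on not-AF
DEFAULT_NON_AF_MIX = {
    RhythmClass.SINUS: 0.9601,
    RhythmClass.SINUS_APC: 0.0164,
    RhythmClass.SINUS_VPC: 0.0204,
    RhythmClass.SINUS_APC_VPC: 0.0010,
    RhythmClass.JUNCTIONAL: 0.0011,
    RhythmClass.PACED: 0.0010,
}

#: fraction of AF records that also carry VPCs (3 of 22 in a screening cohort)
DEFAULT_AF_VPC_FRACTION = 3.0 / 22.0

#: recording-quality class mix of a supervised screening setting
DEFAULT_GRADE_MIX = {"0": 0.835, "1": 0.128, "2a": 0.027, "2b": 0.008, "3": 0.002}


@dataclass
class CohortSpec:
    """Population-level parameters for a synthetic screening cohort."""

    n_subjects: int = 500
    age_mean: float = 58.1
    age_sd: float = 15.0
    age_bounds: tuple[float, float] = (20.0, 95.0)
    #: AF probability per age stratum (boundary: >65 is the elderly stratum)
    prevalence_le65: float = 0.008
    prevalence_gt65: float = 0.042
    age_split: float = 65.0
    non_af_mix: dict = field(default_factory=lambda: dict(DEFAULT_NON_AF_MIX))
    af_vpc_fraction: float = DEFAULT_AF_VPC_FRACTION
    grade_mix: dict = field(default_factory=lambda: dict(DEFAULT_GRADE_MIX))
    #: probability that a subject contributes a second recording
    repeat_rate: float = 0.04
    #: probability of the low-QRS-voltage morphology (<0.5 mV), a known FP driver
    low_voltage_rate: float = 0.05
    male_fraction: float = 0.366
    duration: float = 15.0
    fs: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise InvalidParameterError("n_subjects must be positive")
        for name in ("prevalence_le65", "prevalence_gt65", "repeat_rate",
                     "low_voltage_rate", "male_fraction", "af_vpc_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")
        for mix in (self.non_af_mix, self.grade_mix):
            if any(p < 0 for p in mix.values()):
                raise InvalidParameterError("mixture probabilities must be >= 0")


# --------------------------------------------------------------------------
# RR interval generation


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    lo, hi = RR_BOUNDS
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _truncated_gamma(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    # Gamma with shape k = 1/cv^2 has the requested coefficient of variation.
    lo, hi = RR_BOUNDS
    shape = 1.0 / cv**2
    scale = mean / shape
    out = rng.gamma(shape, scale, size=n)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.gamma(shape, scale, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_rr_sequence(
    spec: RhythmSpec,
    duration: float = 15.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the beat schedule for one recording.

    Returns ``(r_times, beat_types)``: strictly increasing R-peak times in
    seconds (first beat at a fixed start offset) and one label per beat
    ("N", "A" or "V").  Sinus and junctional/paced rhythms draw
    low-variability intervals around 60/mean_hr; AF draws i.i.d. from a
    Gamma distribution with CV ≈ 0.24 truncated to physiologic bounds —
    the irregularly-irregular pattern.  Ectopic classes then replace
    ``round(ectopy_rate)`` normal intervals with a premature beat: APCs get
    a non-compensatory pause, VPCs a fully compensatory one.
    """
    if duration <= 0:
        raise InvalidParameterError(f"duration must be positive, got {duration}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    mean_rr = 60.0 / spec.mean_hr
    cv = spec.effective_rr_cv
    budget = duration - FIRST_BEAT_OFFSET - END_MARGIN
    n_draw = max(int(np.ceil(budget / max(mean_rr * (1 - 3 * cv), RR_BOUNDS[0]))) + 4, 8)

    if spec.rhythm_class.is_af:
        pool = _truncated_gamma(rng, mean_rr, max(cv, 1e-6), n_draw)
    elif cv == 0:
        pool = np.full(n_draw, mean_rr)
    else:
        pool = _truncated_normal(rng, mean_rr, cv * mean_rr, n_draw)

    rr: list[float] = []
    total = 0.0
    i = 0
    while True:
        if i >= pool.size:
            pool = np.concatenate([pool, _truncated_gamma(rng, mean_rr, max(cv, 1e-6), 8)
                                   if spec.rhythm_class.is_af
                                   else _truncated_normal(rng, mean_rr, max(cv, 1e-9) * mean_rr, 8)])
        nxt = pool[i]
        if total + nxt > budget:
            break
        rr.append(float(nxt))
        total += nxt
        i += 1

    n_beats = len(rr) + 1
    beat_types = np.array(["N"] * n_beats, dtype=object)

    ect_type = spec.rhythm_class.ectopic_type
    n_ect = int(round(spec.ectopy_rate)) if ect_type is not None else 0
    if n_ect > 0 and len(rr) >= 2:
        rr_arr = np.array(rr)
        # candidate intervals to split: not the final one (pause must fit)
        candidates = np.arange(0, len(rr_arr) - 1)
        n_ect = min(n_ect, candidates.size // 2)
        chosen = np.sort(rng.choice(candidates, size=n_ect, replace=False))
        # drop adjacent picks: a pause cannot itself host an ectopic beat
        keep = [chosen[0]] if n_ect else []
        for c in chosen[1:]:
            if c > keep[-1] + 1:
                keep.append(c)
        new_rr: list[float] = []
        new_types: list[str] = ["N"]
        mixed = spec.rhythm_class is RhythmClass.SINUS_APC_VPC
        for j, interval in enumerate(rr_arr):
            if j in keep:
                this_type = ect_type if not mixed else ("A" if rng.random() < 0.5 else "V")
                coupling = 0.55 * interval
                if this_type == "A":
                    pause = 0.95 * mean_rr  # non-compensatory: reset of the sinus node
                else:
                    pause = 2.0 * interval - coupling  # compensatory pause
                new_rr.extend([coupling, pause])
                new_types.extend([this_type, "N"])
            else:
                new_rr.append(float(interval))
                new_types.append("N")
        rr = new_rr
        beat_types = np.array(new_types, dtype=object)

    r_times = FIRST_BEAT_OFFSET + np.concatenate([[0.0], np.cumsum(rr)])
    r_times = r_times[r_times <= duration - END_MARGIN]
    beat_types = beat_types[: r_times.size]
    return r_times, beat_types


# --------------------------------------------------------------------------
# Waveform rendering

# Template shares of the nominal QRS peak-to-trough amplitude.  Chosen so the
# rendered peak-to-trough of the summed Gaussians equals qrs_amplitude to
# within a few percent (Q and R tails partially fill the S trough).
_R_SHARE, _Q_SHARE, _S_SHARE = 0.82, 0.06, 0.20
_Q_OFFSET, _S_OFFSET = -0.024, 0.024  # s relative to the R peak
_P_OFFSET = -0.16  # s, P-wave centre before the R peak
_T_OFFSET = 0.28  # s, T-wave centre after the R peak
_NARROW_WIDTH = 0.008  # Gaussian sigma of Q and S waves (s)


def _gauss(t: np.ndarray, center: float, sigma: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def synthesize_ecg(
    r_times: np.ndarray,
    beat_types: np.ndarray,
    wf: WaveformParams,
    rhythm_class: RhythmClass = RhythmClass.SINUS,
    fs: float = 500.0,
    duration: float = 15.0,
    rng: np.random.Generator | None = None,
    subject_id: str = "anon",
    record_id: str = "rec0",
    age: float | None = None,
) -> ECGRecord:
    """Render a beat schedule into a sampled voltage trace.

    Each beat is a sum of Gaussian waves (P unless the rhythm suppresses
    it, Q/R/S, T).  AF classes render continuous amplitude-modulated
    f-waves at ``f_wave_freq`` instead of P waves; VPC beats are wide and
    large with a discordant T; paced beats carry a narrow pacing spike
    before the QRS.  The exact R-peak times go into the truth block.
    """
    r_times = np.asarray(r_times, dtype=float)
    if r_times.size == 0:
        raise InvalidParameterError("beat schedule is empty")
    if fs < 100.0:
        raise InvalidParameterError(f"fs must be >= 100 Hz to resolve the QRS, got {fs}")
    if wf.qrs_width * fs < 2.0:
        raise InvalidParameterError("sampling rate too low to resolve qrs_width")
    if rng is None:
        rng = np.random.default_rng(0)
    rhythm_class = RhythmClass(rhythm_class)

    n = int(round(fs * duration))
    t = np.arange(n) / fs
    x = np.zeros(n)

    p_amp = wf.p_amplitude if rhythm_class.has_p_waves else 0.0

    for r, btype in zip(r_times, beat_types):
        if btype == "V":
            # wide, large, no P, discordant T
            x += _gauss(t, r, 2.6 * wf.qrs_width, 1.3 * _R_SHARE * wf.qrs_amplitude)
            x += _gauss(t, r + 0.055, 0.02, -0.45 * wf.qrs_amplitude)
            x += _gauss(t, r + _T_OFFSET + 0.06, 1.4 * wf.t_width, -1.2 * wf.t_amplitude)
            continue
        # normal (or atrial-premature) narrow complex
        if p_amp > 0 and btype == "N":
            x += _gauss(t, r + _P_OFFSET, wf.p_width, p_amp)
        if rhythm_class is RhythmClass.PACED:
            x += _gauss(t, r - 0.045, 0.002, 0.8)  # pacing spike
        x += _gauss(t, r + _Q_OFFSET, _NARROW_WIDTH, -_Q_SHARE * wf.qrs_amplitude)
        x += _gauss(t, r, wf.qrs_width, _R_SHARE * wf.qrs_amplitude)
        x += _gauss(t, r + _S_OFFSET, _NARROW_WIDTH, -_S_SHARE * wf.qrs_amplitude)
        x += _gauss(t, r + _T_OFFSET, wf.t_width, wf.t_amplitude)

    if rhythm_class.is_af and wf.f_wave_amplitude > 0:
        # continuous fibrillatory waves: amplitude- and phase-modulated sinusoid
        phi = rng.uniform(0, 2 * np.pi)
        am = 1.0 + 0.3 * np.sin(2 * np.pi * 0.9 * t + rng.uniform(0, 2 * np.pi))
        pm = 0.6 * np.sin(2 * np.pi * 0.7 * t + rng.uniform(0, 2 * np.pi))
        x += wf.f_wave_amplitude * am * np.sin(2 * np.pi * wf.f_wave_freq * t + phi + pm)

    truth = RecordTruth(
        rhythm=rhythm_class.value,
        r_peaks=r_times.copy(),
        beat_types=np.asarray(beat_types, dtype=object).copy(),
    )
    return ECGRecord(samples=x, fs=fs, subject_id=subject_id, record_id=record_id,
                     age=age, truth=truth)


# --------------------------------------------------------------------------
# Artifacts


def add_artifacts(rec: ECGRecord, noise: NoiseSpec,
                  rng: np.random.Generator | None = None) -> ECGRecord:
    """Add baseline wander, broadband noise and burst corruption to a record.

    A zero-noise spec returns samples identical to the input.  Burst
    corruption covers one contiguous stretch of exactly
    ``corrupted_fraction`` of the duration (uniform random start); its
    boundaries are recorded in the truth block.
    """
    if noise.is_identity:
        return rec.with_samples(rec.samples.copy())
    if rng is None:
        rng = np.random.default_rng(noise.seed)

    t = rec.times
    x = rec.samples.copy()
    if noise.baseline_wander_amplitude > 0:
        phi = rng.uniform(0, 2 * np.pi)
        x += noise.baseline_wander_amplitude * np.sin(
            2 * np.pi * noise.baseline_wander_freq * t + phi)
    if noise.broadband_noise_sd > 0:
        x += rng.normal(0.0, noise.broadband_noise_sd, size=x.size)

    corrupted: list[tuple[float, float]] = []
    if noise.corrupted_fraction > 0:
        dur = rec.duration
        seg = noise.corrupted_fraction * dur
        start = 0.0 if seg >= dur else float(rng.uniform(0.0, dur - seg))
        i0, i1 = int(round(start * rec.fs)), int(round((start + seg) * rec.fs))
        i1 = min(i1, x.size)
        x[i0:i1] += rng.normal(0.0, noise.burst_noise_sd, size=i1 - i0)
        corrupted.append((i0 / rec.fs, i1 / rec.fs))

    out = rec.with_samples(x)
    if out.truth is not None:
        out.truth = replace(out.truth,
                            corrupted_intervals=out.truth.corrupted_intervals + corrupted)
    elif corrupted:
        out.truth = RecordTruth(rhythm="UNKNOWN", corrupted_intervals=corrupted)
    return out


# --------------------------------------------------------------------------
# Per-record and cohort generation

#: noise parameters injected per target quality class
_GRADE_NOISE = {
    "0": dict(baseline_wander_amplitude=0.02, broadband_noise_sd=0.01, corrupted_fraction=0.0),
    "1": dict(baseline_wander_amplitude=0.10, broadband_noise_sd=0.03, corrupted_fraction=(0.07, 0.25)),
    "2a": dict(baseline_wander_amplitude=0.15, broadband_noise_sd=0.04, corrupted_fraction=(0.36, 0.60)),
    "2b": dict(baseline_wander_amplitude=0.30, broadband_noise_sd=0.05, corrupted_fraction=(0.70, 0.92)),
    "3": dict(baseline_wander_amplitude=0.50, broadband_noise_sd=0.10, corrupted_fraction=1.0,
              burst_noise_sd=2.5),
}


def _noise_for_grade(grade_class: str, seed: int, rng: np.random.Generator) -> NoiseSpec:
    params = dict(_GRADE_NOISE[grade_class])
    cf = params["corrupted_fraction"]
    if isinstance(cf, tuple):
        params["corrupted_fraction"] = float(rng.uniform(*cf))
    return NoiseSpec(seed=seed, **params)


def generate_record(
    rhythm_spec: RhythmSpec,
    wf: WaveformParams | None = None,
    noise: NoiseSpec | None = None,
    fs: float = 500.0,
    duration: float = 15.0,
    subject_id: str = "anon",
    record_id: str = "rec0",
    age: float | None = None,
) -> ECGRecord:
    """Convenience wrapper: RR schedule -> waveform -> artifacts, one seed."""
    rng = np.random.default_rng(rhythm_spec.seed)
    wf = wf if wf is not None else WaveformParams()
    r_times, beat_types = generate_rr_sequence(rhythm_spec, duration, rng)
    rec = synthesize_ecg(r_times, beat_types, wf, rhythm_spec.rhythm_class, fs,
                         duration, rng, subject_id, record_id, age)
    if noise is not None:
        rec = add_artifacts(rec, noise, rng)
    return rec


def _draw_categorical(rng: np.random.Generator, mix: dict) -> object:
    keys = list(mix.keys())
    p = np.array([mix[k] for k in keys], dtype=float)
    p = p / p.sum()
    return keys[int(rng.choice(len(keys), p=p))]


def generate_cohort(spec: CohortSpec) -> tuple[list[ECGRecord], pd.DataFrame]:
    """Generate a full screening cohort and its manifest.

    Ages are drawn from a clipped normal; AF status per subject follows the
    age-stratum prevalences; non-AF subjects get a rhythm from the
    conditional community mix.  A small fraction of subjects contribute a
    second recording (same subject, fresh tracing), giving distinct
    per-ECG and per-subject denominators.  Each record gets a target
    quality class whose noise parameters are injected.  Fully reproducible
    from the master seed.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ECGRecord] = []
    rows: list[dict] = []

    rec_counter = 0
    for s in range(spec.n_subjects):
        subject_id = f"S{s:05d}"
        age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), *spec.age_bounds))
        sex = "M" if rng.random() < spec.male_fraction else "F"
        prev = spec.prevalence_gt65 if age > spec.age_split else spec.prevalence_le65
        is_af = rng.random() < prev
        if is_af:
            rc = (RhythmClass.AF_VPC if rng.random() < spec.af_vpc_fraction
                  else RhythmClass.AF)
        else:
            rc = RhythmClass(_draw_categorical(rng, spec.non_af_mix))
        n_rec = 2 if rng.random() < spec.repeat_rate else 1

        mean_hr = (float(np.clip(rng.normal(90, 15), 60, 140)) if rc.is_af
                   else float(np.clip(rng.normal(72, 10), 45, 110)))
        low_voltage = rng.random() < spec.low_voltage_rate
        qrs_amp = float(rng.uniform(0.3, 0.45)) if low_voltage else float(rng.uniform(0.8, 1.6))
        wf = WaveformParams(
            p_amplitude=float(rng.uniform(0.10, 0.20)),
            qrs_amplitude=qrs_amp,
            t_amplitude=float(rng.uniform(0.15, 0.35)),
        )
        ectopy = float(rng.integers(2, 6)) if rc.ectopic_type is not None else 0.0

        for _ in range(n_rec):
            rec_seed = int(rng.integers(0, 2**31 - 1))
            grade_class = str(_draw_categorical(rng, spec.grade_mix))
            rec_rng = np.random.default_rng(rec_seed)
            noise = _noise_for_grade(grade_class, rec_seed, rec_rng)
            record_id = f"R{rec_counter:05d}"
            rspec = RhythmSpec(rhythm_class=rc, mean_hr=mean_hr, ectopy_rate=ectopy,
                               seed=rec_seed)
            rec = generate_record(rspec, wf, noise, fs=spec.fs, duration=spec.duration,
                                  subject_id=subject_id, record_id=record_id, age=age)
            rec.truth.grade_class = grade_class
            records.append(rec)
            rows.append(dict(record_id=record_id, subject_id=subject_id, age=age,
                             sex=sex, true_rhythm=rc.value, grade_class=grade_class,
                             seed=rec_seed))
            rec_counter += 1

    manifest = pd.DataFrame(rows)
    return records, manifest
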