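"""Rhythm feature extraction: R-peaks, RR statistics, P-wave presence, QRS voltage.

These are the inputs of the AF decision rule ("irregular RR intervals and
no discernible, distinct P waves") plus the low-QRS-voltage feature that
drives false positives.  QRS detection is an energy detector in the
Pan-Tompkins tradition: band-pass, differentiate, square, moving-window
integrate, adaptive threshold with a 200 ms refractory period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import InsufficientBeatsError
from .records import ECGRecord

__all__ = [
    "FeatureVector",
    "detect_qrs",
    "rr_statistics",
    "p_wave_score",
    "qrs_amplitude",
    "extract_features",
    "mask_to_sample_bool",
]

#: minimum spacing between detected R peaks (s)
REFRACTORY = 0.2
#: P-wave search window relative to the R peak (s)
P_WINDOW = (-0.250, -0.080)
#: successive-RR-difference threshold for the pNN50-style fraction (s)
DELTA_RR_THRESHOLD = 0.050
#: absolute P-wave amplitude floor (mV)
P_AMP_FLOOR = 0.05
#: per-beat P-peak timing must sit within this of the cohort median offset (s)
P_TIMING_TOL = 0.030
#: the P window may not start before this much after the previous R peak,
#: keeping the previous beat's T wave out of the P search (s)
T_CLEARANCE = 0.36
#: minimum usable P-window length after clipping (s)
P_WINDOW_MIN = 0.06
#: P peak must dominate its window: max >= this multiple of the window RMS.
#: A Gaussian P bump has a crest factor ~2; a sinusoidal f-wave only sqrt(2).
P_DOMINANCE = 1.9


@dataclass
class FeatureVector:
    """Per-record extracted features; statistics are None when uncomputable."""

    r_peaks: np.ndarray = field(default_factory=lambda: np.empty(0))
    rr: np.ndarray = field(default_factory=lambda: np.empty(0))
    rr_cv: float | None = None
    rr_rmssd_norm: float | None = None
    pct_delta_rr_gt: float | None = None
    p_score: float | None = None
    qrs_amp: float | None = None

    @property
    def n_beats(self) -> int:
        return int(self.r_peaks.size)

    @property
    def valid(self) -> bool:
        """Whether enough beats were usable for rhythm classification."""
        return self.rr_cv is not None and self.p_score is not None


def mask_to_sample_bool(rec: ECGRecord, intervals: list[tuple[float, float]]) -> np.ndarray:
    """Convert (start_s, end_s) intervals into a per-sample boolean mask."""
    m = np.zeros(rec.samples.size, dtype=bool)
    for t0, t1 in intervals:
        i0 = max(int(np.floor(t0 * rec.fs)), 0)
        i1 = min(int(np.ceil(t1 * rec.fs)), m.size)
        m[i0:i1] = True
    return m


def _bandpass(x: np.ndarray, fs: float, lo: float = 5.0, hi: float = 25.0) -> np.ndarray:
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def detect_qrs(rec: ECGRecord, mask: np.ndarray | None = None) -> np.ndarray:
    """Detect R-peak times (s), strictly increasing, >= 200 ms apart.

    ``mask`` marks samples known to be artifact-corrupted; they are zeroed
    before detection so bursts cannot masquerade as beats.  An empty array
    is a valid result (flat or fully-corrupted records).
    """
    x = rec.samples.astype(float).copy()
    if mask is not None:
        x[mask] = 0.0
    if not np.any(x):
        return np.empty(0)

    fs = rec.fs
    bp = _bandpass(x, fs)
    der = np.gradient(bp) * fs
    sq = der * der
    win = max(int(round(0.12 * fs)), 1)
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    distance = max(int(round(REFRACTORY * fs)), 1)
    cand, props = signal.find_peaks(integ, distance=distance, height=0.0)
    if cand.size == 0:
        return np.empty(0)
    heights = props["peak_heights"]
    # adaptive threshold: a fixed fraction of the upper height quantile keeps
    # every true beat (beat heights are comparable) and rejects T-wave/noise bumps
    thr = 0.20 * np.percentile(heights, 90)
    cand = cand[heights >= thr]
    if cand.size == 0:
        return np.empty(0)

    # refine each detection to the largest absolute band-passed excursion nearby
    half = int(round(0.10 * fs))
    refined = []
    for c in cand:
        a, b = max(c - half, 0), min(c + half + 1, bp.size)
        refined.append(a + int(np.argmax(np.abs(bp[a:b]))))
    refined = np.unique(refined)

    # enforce the refractory period after refinement, keeping the stronger peak
    kept: list[int] = []
    for idx in refined:
        if kept and idx - kept[-1] < distance:
            if np.abs(bp[idx]) > np.abs(bp[kept[-1]]):
                kept[-1] = idx
        else:
            kept.append(idx)
    return np.asarray(kept, dtype=float) / fs


def rr_statistics(rr: np.ndarray) -> tuple[float, float, float]:
    """RR irregularity statistics: (CV, RMSSD/mean, fraction of |ΔRR| > 50 ms).

    CV uses the sample standard deviation (n−1 denominator).  Requires at
    least 3 intervals; shorter sequences cannot be auto-classified.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 3:
        raise InsufficientBeatsError(f"need >= 3 RR intervals, got {rr.size}")
    mean = float(np.mean(rr))
    cv = float(np.std(rr, ddof=1) / mean)
    d = np.diff(rr)
    rmssd = float(np.sqrt(np.mean(d * d)))
    pct = float(np.mean(np.abs(d) > DELTA_RR_THRESHOLD))
    return cv, rmssd / mean, pct


def p_wave_score(rec: ECGRecord, r_peaks: np.ndarray,
                 mask: np.ndarray | None = None) -> float:
    """Fraction of beats with a discernible, distinct P wave, in [0, 1].

    For each beat the window [R−250 ms, R−80 ms] is examined (beats whose
    window leaves the record or touches masked samples are skipped).  A
    beat counts as P-positive when its dominant positive deflection
    (1) exceeds max(0.05 mV, 2× the local noise SD), (2) dominates the
    window (max ≥ 1.9× window RMS — a sinusoidal f-wave fails this), and
    (3) peaks within 30 ms of the median P offset across beats (random
    f-wave/noise peaks fail this).  Deterministic.
    """
    r_peaks = np.asarray(r_peaks, dtype=float)
    if r_peaks.size < 3:
        raise InsufficientBeatsError(f"need >= 3 beats for a P-wave score, got {r_peaks.size}")
    fs = rec.fs
    x = rec.samples

    offsets: list[float] = []
    amp_ok: list[bool] = []
    for k, r in enumerate(r_peaks):
        start = r + P_WINDOW[0]
        if k > 0:  # keep the previous beat's T wave out of the search window
            start = max(start, r_peaks[k - 1] + T_CLEARANCE)
        if (r + P_WINDOW[1]) - start < P_WINDOW_MIN:
            continue
        i0 = int(round(start * fs))
        i1 = int(round((r + P_WINDOW[1]) * fs))
        if i0 < 0 or i1 > x.size or i1 - i0 < 4:
            continue
        if mask is not None and np.any(mask[i0:i1]):
            continue
        raw = x[i0:i1] - np.median(x[i0:i1])
        # robust local noise SD from first differences (smooth waves barely move it)
        dn = np.abs(np.diff(raw))
        noise_sd = 1.4826 * float(np.median(dn)) / np.sqrt(2.0)
        # a P wave is a 60-120 ms bump: smooth with a ~20 ms boxcar so broadband
        # noise spikes cannot masquerade as a dominant deflection
        klen = max(int(round(0.02 * fs)), 1)
        w = np.convolve(raw, np.ones(klen) / klen, mode="same")
        w = w - np.median(w)
        peak_idx = int(np.argmax(w))
        v = float(w[peak_idx])
        rms = float(np.sqrt(np.mean(w * w))) if w.size else 0.0
        ok = v >= max(P_AMP_FLOOR, 2.0 * noise_sd) and (rms == 0.0 or v >= P_DOMINANCE * rms)
        amp_ok.append(ok)
        offsets.append((i0 + peak_idx) / fs - r)  # P-peak offset relative to R

    if len(offsets) < 3:
        raise InsufficientBeatsError("fewer than 3 beats with an intact P-search window")

    offsets_arr = np.asarray(offsets)
    ok_arr = np.asarray(amp_ok)
    if not np.any(ok_arr):
        return 0.0
    med = float(np.median(offsets_arr[ok_arr]))
    hits = ok_arr & (np.abs(offsets_arr - med) <= P_TIMING_TOL)
    return float(np.mean(hits))


def qrs_amplitude(rec: ECGRecord, r_peaks: np.ndarray) -> float:
    """Median peak-to-trough voltage (mV) within ±60 ms of each R peak."""
    r_peaks = np.asarray(r_peaks, dtype=float)
    if r_peaks.size == 0:
        raise InsufficientBeatsError("no detected beats")
    fs = rec.fs
    amps = []
    for r in r_peaks:
        i0 = max(int(round((r - 0.060) * fs)), 0)
        i1 = min(int(round((r + 0.060) * fs)), rec.samples.size)
        if i1 - i0 < 2:
            continue
        w = rec.samples[i0:i1]
        amps.append(float(np.max(w) - np.min(w)))
    if not amps:
        raise InsufficientBeatsError("no usable QRS windows")
    return float(np.median(amps))


def _usable_rr(r_peaks: np.ndarray, rec: ECGRecord,
               mask: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Drop peaks inside masked stretches and RR intervals spanning them."""
    if mask is None or not mask.any():
        return r_peaks, np.diff(r_peaks)
    idx = np.clip((r_peaks * rec.fs).astype(int), 0, mask.size - 1)
    clean_peaks = r_peaks[~mask[idx]]
    rr = []
    for a, b in zip(clean_peaks[:-1], clean_peaks[1:]):
        ia, ib = int(a * rec.fs), int(b * rec.fs)
        if not np.any(mask[ia:ib]):
            rr.append(b - a)
    return clean_peaks, np.asarray(rr)


def extract_features(rec: ECGRecord, mask: np.ndarray | None = None) -> FeatureVector:
    """Run the full feature stage on a (baseline-removed) record.

    Returns a FeatureVector whose statistics are None when fewer than 3
    usable beats/intervals exist — the record is then ungradable rather
    than an error, mirroring how a screening pipeline must keep going.
    """
    r_peaks = detect_qrs(rec, mask)
    fv = FeatureVector(r_peaks=r_peaks)
    if r_peaks.size == 0:
        return fv
    clean_peaks, rr = _usable_rr(r_peaks, rec, mask)
    fv.rr = rr
    try:
        fv.qrs_amp = qrs_amplitude(rec, clean_peaks if clean_peaks.size else r_peaks)
    except InsufficientBeatsError:
        fv.qrs_amp = None
    try:
        fv.rr_cv, fv.rr_rmssd_norm, fv.pct_delta_rr_gt = rr_statistics(rr)
    except InsufficientBeatsError:
        pass
    try:
        fv.p_score = p_wave_score(rec, clean_peaks, mask)
    except InsufficientBeatsError:
        pass
    return fv
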