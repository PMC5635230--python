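"""Recording-quality grading on the five-level artifact scale 0/1/2a/2b/3.

The scale mirrors how an over-reading cardiologist grades single-lead
screening tracings:

* grade 0  — excellent quality, no artifacts;
* grade 1  — artifact percentage < 33% with recognizable P waves;
* grade 2a — artifact percentage 33–66%, or mild baseline wander, with
  recognizable P waves;
* grade 2b — artifact percentage > 66%, or significant wander interfering
  with P-wave recognition;
* grade 3  — significant artifacts without recognizable P waves or QRS
  complexes (excluded from performance analysis downstream).

"Artifact percentage" is operationalized as the time fraction of 1-second
windows flagged for excess broadband noise power or clipping.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .features import FeatureVector
from .records import ECGRecord

__all__ = ["Grade", "QualityGrade", "artifact_windows", "artifact_fraction",
           "artifact_mask", "wander_level", "grade_quality"]


class Grade(str, enum.Enum):
    G0 = "0"
    G1 = "1"
    G2A = "2a"
    G2B = "2b"
    G3 = "3"


#: analysis window for artifact flagging (s)
WINDOW_S = 1.0
#: RMS of >40 Hz content above which a window is flagged (mV); QRS energy
#: lives below ~40 Hz, so this catches burst/EMG noise, not beats
HF_RMS_THRESHOLD = 0.15
#: absolute voltage beyond which a window counts as clipped/saturated (mV)
CLIP_LEVEL = 3.0
#: residual sub-0.5 Hz RMS bounds separating none / mild / significant wander (mV)
WANDER_MILD = 0.05
WANDER_SIGNIFICANT = 0.20
#: grade-0 requires a near-zero artifact fraction
G0_MAX_FRACTION = 0.05
#: P waves count as recognizable above this score
P_RECOGNIZABLE = 0.5
#: a record needs this many usable beats for its QRS to count as recognizable
MIN_BEATS = 3


@dataclass
class QualityGrade:
    grade: Grade
    artifact_fraction: float
    p_recognizable: bool
    qrs_recognizable: bool
    wander_flag: str  # "none" | "mild" | "significant"


#: sub-window resolution used inside each 1 s window (s)
SUBWINDOW_S = 0.25


def artifact_windows(rec: ECGRecord) -> np.ndarray:
    """Boolean flag per 1 s window: excess high-frequency power or clipping.

    Each window is judged by majority vote over 0.25 s sub-windows, so a
    corruption burst that only clips a window's edge does not flag the
    whole window — the measured fraction tracks the true corrupted time
    to within one window.
    """
    n_win = max(int(np.floor(rec.duration / WINDOW_S)), 1)
    wlen = int(round(WINDOW_S * rec.fs))
    slen = int(round(SUBWINDOW_S * rec.fs))
    per_win = max(wlen // slen, 1)
    sos = signal.butter(2, 40.0, btype="highpass", fs=rec.fs, output="sos")
    hf = signal.sosfiltfilt(sos, rec.samples)
    flags = np.zeros(n_win, dtype=bool)
    for k in range(n_win):
        bad = 0
        for j in range(per_win):
            seg = slice(k * wlen + j * slen,
                        min(k * wlen + (j + 1) * slen, rec.samples.size))
            if seg.start >= rec.samples.size:
                break
            rms = float(np.sqrt(np.mean(hf[seg] ** 2)))
            clipped = float(np.max(np.abs(rec.samples[seg]))) > CLIP_LEVEL
            bad += (rms > HF_RMS_THRESHOLD) or clipped
        flags[k] = bad * 2 > per_win
    return flags


def artifact_fraction(rec: ECGRecord) -> float:
    """Time fraction of the recording carrying flagged artifact windows."""
    flags = artifact_windows(rec)
    return float(np.mean(flags))


def artifact_mask(rec: ECGRecord) -> np.ndarray:
    """Per-sample boolean mask over the flagged 1 s windows."""
    flags = artifact_windows(rec)
    wlen = int(round(WINDOW_S * rec.fs))
    m = np.zeros(rec.samples.size, dtype=bool)
    for k, f in enumerate(flags):
        if f:
            m[k * wlen:(k + 1) * wlen] = True
    return m


def wander_level(rec: ECGRecord) -> str:
    """Classify residual sub-0.5 Hz baseline content as none/mild/significant."""
    sos = signal.butter(2, 0.5, btype="lowpass", fs=rec.fs, output="sos")
    lf = signal.sosfiltfilt(sos, rec.samples - np.mean(rec.samples))
    rms = float(np.sqrt(np.mean(lf * lf)))
    if rms < WANDER_MILD:
        return "none"
    if rms < WANDER_SIGNIFICANT:
        return "mild"
    return "significant"


def grade_quality(rec: ECGRecord, features: FeatureVector,
                  fraction: float | None = None,
                  wander: str | None = None) -> QualityGrade:
    """Assign the artifact grade from the measured fraction and P/QRS flags.

    Deterministic; every record receives exactly one grade, and increasing
    the artifact fraction with flags held fixed never improves it.  Grade 3
    is the sink for records without a recognizable QRS.
    """
    f = artifact_fraction(rec) if fraction is None else float(fraction)
    w = wander_level(rec) if wander is None else wander
    p_rec = features.p_score is not None and features.p_score >= P_RECOGNIZABLE
    qrs_rec = features.n_beats >= MIN_BEATS and features.rr_cv is not None

    if not qrs_rec:
        g = Grade.G3
    elif f <= G0_MAX_FRACTION and w == "none":
        g = Grade.G0
    elif f < 1.0 / 3.0 and p_rec and w != "significant":
        g = Grade.G1
    elif (f <= 2.0 / 3.0 or w == "mild") and p_rec and w != "significant":
        g = Grade.G2A
    else:
        g = Grade.G2B
    return QualityGrade(grade=g, artifact_fraction=f, p_recognizable=p_rec,
                        qrs_recognizable=qrs_rec, wander_flag=w)
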