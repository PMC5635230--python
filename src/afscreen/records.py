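"""ECG record container and plain-text I/O.

A record is one 15-second single-lead tracing in millivolts.  Synthetic
records carry a ground-truth block (rhythm class, exact R-peak times, beat
labels, corrupted time intervals) so every downstream stage can be scored
against construction truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = ["RecordTruth", "ECGRecord", "write_record_csv", "read_record_csv"]


@dataclass
class RecordTruth:
    """Construction ground truth attached to a synthetic record."""

    rhythm: str
    r_peaks: np.ndarray = field(default_factory=lambda: np.empty(0))
    #: per-beat label: "N" normal, "A" atrial premature, "V" ventricular premature
    beat_types: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    #: (start_s, end_s) intervals carrying injected burst corruption
    corrupted_intervals: list[tuple[float, float]] = field(default_factory=list)
    grade_class: str | None = None

    @property
    def n_ectopic(self) -> int:
        return int(np.sum(np.isin(self.beat_types, ["A", "V"])))


@dataclass
class ECGRecord:
    """One single-lead ECG: voltage samples (mV) at a fixed sampling rate."""

    samples: np.ndarray
    fs: float
    subject_id: str = "anon"
    record_id: str = "rec0"
    age: float | None = None
    truth: RecordTruth | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise InvalidInputError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise InvalidInputError("samples must be a 1-D voltage sequence")

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray) -> "ECGRecord":
        """Copy of this record with replaced voltage samples (same length)."""
        return replace(self, samples=np.asarray(samples, dtype=float))


def write_record_csv(rec: ECGRecord, path: str | Path) -> None:
    """Write a record as CSV with header ``t_s,mv``, one row per sample."""
    df = pd.DataFrame({"t_s": rec.times, "mv": rec.samples})
    df.to_csv(path, index=False, float_format="%.6f")


def read_record_csv(path: str | Path, record_id: str | None = None) -> ECGRecord:
    """Read a ``t_s,mv`` CSV back into a record; fs inferred from sample spacing."""
    df = pd.read_csv(path)
    if not {"t_s", "mv"} <= set(df.columns):
        raise InvalidInputError(f"{path}: expected columns t_s,mv")
    t = df["t_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise InvalidInputError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-4, atol=1e-9):
        raise InvalidInputError(f"{path}: sample times are not uniformly spaced")
    rid = record_id if record_id is not None else Path(path).stem
    return ECGRecord(samples=df["mv"].to_numpy(dtype=float), fs=1.0 / dt[0], record_id=rid)
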