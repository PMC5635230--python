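"""Rule-based AF decision: irregular RR intervals AND no distinct P waves.

The deployed decision is deliberately binary — it does not attempt to
label atrial or ventricular premature complexes.  The conjunction is what
keeps ectopy (APC/VPC with preserved P waves) from flooding the positive
calls: RR irregularity alone would flag most of them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .errors import CalibrationError
from .features import FeatureVector
from .quality import Grade, QualityGrade

__all__ = ["Call", "Thresholds", "AFDecision", "classify_af",
           "calibrate_thresholds", "decide_table"]


class Call(str, enum.Enum):
    AF = "AF"
    NOT_AF = "NOT_AF"
    UNGRADABLE = "UNGRADABLE"


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds: RR-CV, normalized RMSSD, P-score cutoffs."""

    tau_cv: float = 0.12
    tau_rmssd: float = 0.10
    tau_p: float = 0.5


@dataclass
class AFDecision:
    call: Call
    rr_irregular: bool | None
    p_absent: bool | None
    thresholds: Thresholds


def classify_af(features: FeatureVector, grade: QualityGrade | None = None,
                thresholds: Thresholds | None = None) -> AFDecision:
    """Classify one record: AF iff RR-irregular and P-absent.

    Grade-3 records and records with too few usable beats are UNGRADABLE.
    ``rr_irregular`` is an OR of the CV and normalized-RMSSD criteria;
    ``p_absent`` means the P-wave score falls below ``tau_p``.
    """
    thr = thresholds if thresholds is not None else Thresholds()
    if (grade is not None and grade.grade is Grade.G3) or not features.valid:
        return AFDecision(Call.UNGRADABLE, None, None, thr)
    rr_irregular = (features.rr_cv >= thr.tau_cv) or (features.rr_rmssd_norm >= thr.tau_rmssd)
    p_absent = features.p_score < thr.tau_p
    call = Call.AF if (rr_irregular and p_absent) else Call.NOT_AF
    return AFDecision(call, rr_irregular, p_absent, thr)


def decide_table(df: pd.DataFrame, thresholds: Thresholds,
                 rr_only: bool = False) -> np.ndarray:
    """Vectorized decision over a feature table (columns rr_cv,
    rr_rmssd_norm, p_score; NaN marks ungradable records).

    ``rr_only=True`` drops the P-wave requirement — the degraded rule used
    to demonstrate why the conjunction is needed.  Returns an object array
    of Call values.
    """
    cv = df["rr_cv"].to_numpy(dtype=float)
    rm = df["rr_rmssd_norm"].to_numpy(dtype=float)
    ps = df["p_score"].to_numpy(dtype=float)
    gradable = ~(np.isnan(cv) | np.isnan(rm) | np.isnan(ps))
    if "grade" in df.columns:
        gradable &= df["grade"].astype(str).to_numpy() != Grade.G3.value
    rr_irr = (cv >= thresholds.tau_cv) | (rm >= thresholds.tau_rmssd)
    pos = rr_irr if rr_only else (rr_irr & (ps < thresholds.tau_p))
    out = np.where(pos, Call.AF.value, Call.NOT_AF.value).astype(object)
    out[~gradable] = Call.UNGRADABLE.value
    return out


#: calibration search grid
_CV_GRID = np.round(np.arange(0.05, 0.305, 0.01), 3)
_RMSSD_GRID = np.round(np.arange(0.05, 0.305, 0.01), 3)
_P_GRID = np.round(np.arange(0.3, 0.75, 0.1), 2)


def calibrate_thresholds(features: pd.DataFrame, labels: np.ndarray) -> Thresholds:
    """Grid-search (τ_cv, τ_rmssd, τ_p) maximizing Youden's J on a labelled cohort.

    ``labels`` is boolean (True = reference AF) aligned with the feature
    rows; ungradable rows (NaN features) are dropped first.  Many grid
    points usually tie at the maximal J; the most central tied combination
    (marginal medians, snapped to the nearest tied grid point) is returned
    rather than an extreme corner, so the operating point generalizes.
    Fully deterministic given the cohort.
    """
    cv = features["rr_cv"].to_numpy(dtype=float)
    rm = features["rr_rmssd_norm"].to_numpy(dtype=float)
    ps = features["p_score"].to_numpy(dtype=float)
    labels = np.asarray(labels, dtype=bool)
    ok = ~(np.isnan(cv) | np.isnan(rm) | np.isnan(ps))
    cv, rm, ps, y = cv[ok], rm[ok], ps[ok], labels[ok]
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise CalibrationError(
            f"both classes required for calibration (pos={n_pos}, neg={n_neg})")

    best_j, ties = -np.inf, []
    for tcv, trm, tp in product(_CV_GRID, _RMSSD_GRID, _P_GRID):
        pos = ((cv >= tcv) | (rm >= trm)) & (ps < tp)
        sens = np.sum(pos & y) / n_pos
        spec = np.sum(~pos & ~y) / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-9:
            best_j, ties = j, [(tcv, trm, tp)]
        elif j > best_j - 1e-9:
            ties.append((tcv, trm, tp))

    arr = np.array(sorted(ties))
    center = np.median(arr, axis=0)
    scale = np.array([np.ptp(_CV_GRID), np.ptp(_RMSSD_GRID), np.ptp(_P_GRID)])
    dist = np.sum(((arr - center) / scale) ** 2, axis=1)
    best = arr[int(np.argmin(dist))]  # sorted ties: nearest-to-center, then lexicographic
    return Thresholds(*map(float, best))
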