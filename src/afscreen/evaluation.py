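"""Diagnostic-test evaluation: confusion tables, exact CIs, age-stratified report.

Sensitivity and specificity carry exact (Clopper-Pearson) binomial
confidence intervals; the predictive values PPV and NPV carry
logit/delta-method intervals (the standard approach for predictive
values, whose sampling distribution is not a simple binomial of the
column totals).  Percentages are reported to 1 decimal, round-half-up.

``reconstruct_study_table`` rebuilds the published screening study's
stratified performance table from its printed counts: 965 gradable ECGs
(grade-3 excluded), 22 reference-AF with 1 false negative and 22 false
positives overall; stratum false positives are recovered arithmetically
from the printed stratum PPVs.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, InvalidParameterError

__all__ = [
    "ConfusionTable",
    "Metric",
    "StratumReport",
    "PerformanceReport",
    "build_confusion",
    "rates",
    "exact_binomial_ci",
    "predictive_value_ci",
    "round_pct",
    "recover_fp_from_ppv",
    "reconstruct_study_table",
    "render_table1",
    "report_from_confusions",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 screening table for one stratum (counts of records)."""

    tp: int
    fn: int
    fp: int
    tn: int
    stratum: str = "overall"

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise InvalidParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def reference_positives(self) -> int:
        return self.tp + self.fn

    @property
    def test_positives(self) -> int:
        return self.tp + self.fp

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(self.tp + other.tp, self.fn + other.fn,
                              self.fp + other.fp, self.tn + other.tn,
                              stratum="sum")


def round_pct(x: float | None, decimals: int = 1) -> float | None:
    """Round a percentage with ROUND_HALF_UP, as tabulated clinical results are."""
    if x is None:
        return None
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def exact_binomial_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact CI for a binomial proportion, in percent.

    Bounds come from beta-distribution quantiles; the lower bound is 0 at
    zero successes and the upper bound 100 at ``successes == n``.
    """
    if n < 1 or not (0 <= successes <= n):
        raise InvalidParameterError(f"invalid counts: {successes}/{n}")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return 100.0 * lo, 100.0 * hi


def predictive_value_ci(t: ConfusionTable, which: str,
                        level: float = 0.95) -> tuple[float, float] | None:
    """Logit (delta-method) CI for PPV or NPV, in percent.

    The variance of logit(PPV) combines the binomial variances of
    sensitivity (over the diseased) and specificity (over the
    non-diseased); symmetrically for NPV.  Undefined (returns None) when
    the point estimate is exactly 0 or 1 — such cells are reported as the
    bare point estimate.
    """
    n1, n0 = t.reference_positives, t.fp + t.tn  # diseased / non-diseased counts
    if n1 == 0 or n0 == 0:
        return None
    se, sp = t.tp / n1, t.tn / n0
    if which == "ppv":
        denom = t.tp + t.fp
        if denom == 0:
            return None
        p = t.tp / denom
        if p in (0.0, 1.0) or se == 0.0 or sp == 1.0:
            return None
        var = (1 - se) / (se * n1) + sp / ((1 - sp) * n0)
    elif which == "npv":
        denom = t.tn + t.fn
        if denom == 0:
            return None
        p = t.tn / denom
        if p in (0.0, 1.0) or sp == 0.0 or se == 1.0:
            return None
        var = se / ((1 - se) * n1) + (1 - sp) / (sp * n0)
    else:
        raise InvalidParameterError(f"which must be 'ppv' or 'npv', got {which!r}")
    z = float(stats.norm.ppf(1 - (1 - level) / 2))
    logit = np.log(p / (1 - p))
    lo, hi = logit - z * np.sqrt(var), logit + z * np.sqrt(var)
    inv = lambda u: 1.0 / (1.0 + np.exp(-u))
    return 100.0 * inv(lo), 100.0 * inv(hi)


def rates(t: ConfusionTable) -> dict[str, float | None]:
    """Point estimates in percent (unrounded); None marks a zero denominator."""
    def frac(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    return {
        "sensitivity": frac(t.tp, t.tp + t.fn),
        "specificity": frac(t.tn, t.tn + t.fp),
        "ppv": frac(t.tp, t.tp + t.fp),
        "npv": frac(t.tn, t.tn + t.fn),
        "prevalence": frac(t.tp + t.fn, t.total) if t.total else None,
    }


@dataclass
class Metric:
    """One report cell: point estimate (percent) with optional 95% CI."""

    point: float | None
    ci: tuple[float, float] | None = None

    def rounded(self) -> tuple[float | None, tuple[float, float] | None]:
        pt = round_pct(self.point)
        ci = None if self.ci is None else (round_pct(self.ci[0]), round_pct(self.ci[1]))
        return pt, ci

    def render(self) -> str:
        pt, ci = self.rounded()
        if pt is None:
            return "-"
        if ci is None:
            return f"{pt:.1f}"
        return f"{pt:.1f} (95% CI {ci[0]:.1f}%-{ci[1]:.1f}%)"


@dataclass
class StratumReport:
    stratum: str
    table: ConfusionTable
    sensitivity: Metric
    specificity: Metric
    ppv: Metric
    npv: Metric
    prevalence_by_ecg: tuple[int, int]  # (AF records, gradable records)
    prevalence_by_subject: tuple[int, int] | None = None

    @property
    def prevalence_by_ecg_pct(self) -> float:
        n, d = self.prevalence_by_ecg
        return 100.0 * n / d if d else float("nan")

    @property
    def prevalence_by_subject_pct(self) -> float | None:
        if self.prevalence_by_subject is None:
            return None
        n, d = self.prevalence_by_subject
        return 100.0 * n / d if d else None


@dataclass
class PerformanceReport:
    strata: dict[str, StratumReport]  # keys: "le", "gt", "overall"


def stratum_report(t: ConfusionTable,
                   subjects: tuple[int, int] | None = None) -> StratumReport:
    r = rates(t)
    sens = Metric(r["sensitivity"],
                  None if t.reference_positives == 0
                  else exact_binomial_ci(t.tp, t.reference_positives))
    spec_den = t.tn + t.fp
    spec = Metric(r["specificity"],
                  None if spec_den == 0 else exact_binomial_ci(t.tn, spec_den))
    ppv = Metric(r["ppv"], predictive_value_ci(t, "ppv"))
    npv = Metric(r["npv"], predictive_value_ci(t, "npv"))
    return StratumReport(t.stratum, t, sens, spec, ppv, npv,
                         prevalence_by_ecg=(t.reference_positives, t.total),
                         prevalence_by_subject=subjects)


def build_confusion(df: pd.DataFrame, age_split: float = 65.0,
                    exclude_grades: tuple[str, ...] = ("3",)) -> dict[str, ConfusionTable]:
    """Tabulate calls against reference labels, per age stratum.

    ``df`` needs columns ``call`` (AF / NOT_AF / UNGRADABLE), ``is_af``
    (reference label) and ``age``.  Grade-``exclude_grades`` records (if a
    ``grade`` column exists) and UNGRADABLE calls are removed before
    tabulation.  Strata: age <= split, age > split, overall.
    """
    for col in ("call", "is_af", "age"):
        if col not in df.columns:
            raise DataError(f"missing required column {col!r}")
    if df["is_af"].isna().any():
        raise DataError("missing reference label for at least one record")
    d = df.copy()
    if "grade" in d.columns:
        d = d[~d["grade"].astype(str).isin([str(g) for g in exclude_grades])]
    d = d[d["call"] != "UNGRADABLE"]

    def table(sub: pd.DataFrame, name: str) -> ConfusionTable:
        pos = sub["call"] == "AF"
        ref = sub["is_af"].astype(bool)
        return ConfusionTable(tp=int((pos & ref).sum()), fn=int((~pos & ref).sum()),
                              fp=int((pos & ~ref).sum()), tn=int((~pos & ~ref).sum()),
                              stratum=name)

    return {
        "le": table(d[d["age"] <= age_split], f"age<={age_split:g}"),
        "gt": table(d[d["age"] > age_split], f"age>{age_split:g}"),
        "overall": table(d, "overall"),
    }


def report_from_confusions(confusions: dict[str, ConfusionTable],
                           subjects: dict[str, tuple[int, int]] | None = None
                           ) -> PerformanceReport:
    subjects = subjects or {}
    return PerformanceReport(strata={
        k: stratum_report(t, subjects.get(k)) for k, t in confusions.items()
    })


# --------------------------------------------------------------------------
# Published-study reconstruction

#: printed study counts: 965 gradable ECGs, 22 reference-AF (1 FN), 22 FP
STUDY_OVERALL = dict(n=965, ref_af=22, fn=1, fp=22)
#: printed stratum sizes and reference-AF counts (ECG denominators)
STUDY_STRATA = {"le": dict(n=526, ref_af=4, fn=0), "gt": dict(n=439, ref_af=18, fn=1)}
#: printed stratum PPVs, used to recover the unprinted stratum false positives
STUDY_STRATUM_PPV = {"le": 36.4, "gt": 53.1}
#: printed per-subject prevalence denominators (residents screened)
STUDY_SUBJECTS = {"le": (4, 496), "gt": (18, 426), "overall": (22, 922)}


def recover_fp_from_ppv(tp: int, ppv_pct: float) -> int:
    """Invert PPV = tp/(tp+fp): the printed 1-decimal PPV pins fp exactly."""
    if not (0 < ppv_pct <= 100):
        raise InvalidParameterError("ppv_pct must be in (0, 100]")
    return int(round(tp / (ppv_pct / 100.0))) - tp


def reconstruct_study_table() -> PerformanceReport:
    """Rebuild the stratified performance table from the printed counts.

    Stratum FPs are recovered from the printed PPVs and cross-checked:
    they must sum to the printed overall 22 FPs, and the stratum tables
    must add cell-wise to the overall table.
    """
    tables: dict[str, ConfusionTable] = {}
    for key, s in STUDY_STRATA.items():
        tp = s["ref_af"] - s["fn"]
        fp = recover_fp_from_ppv(tp, STUDY_STRATUM_PPV[key])
        tn = s["n"] - s["ref_af"] - fp
        tables[key] = ConfusionTable(tp=tp, fn=s["fn"], fp=fp, tn=tn,
                                     stratum="age<=65" if key == "le" else "age>65")
    o = STUDY_OVERALL
    overall = ConfusionTable(tp=o["ref_af"] - o["fn"], fn=o["fn"], fp=o["fp"],
                             tn=o["n"] - o["ref_af"] - o["fp"], stratum="overall")
    summed = tables["le"] + tables["gt"]
    if (summed.tp, summed.fn, summed.fp, summed.tn) != (overall.tp, overall.fn,
                                                        overall.fp, overall.tn):
        raise DataError("stratum tables do not add up to the overall table")
    tables["overall"] = overall
    return report_from_confusions(tables, subjects=STUDY_SUBJECTS)


_ROW_LABELS = [
    ("sensitivity", "Sensitivity, % (95% CI)"),
    ("specificity", "Specificity, % (95% CI)"),
    ("ppv", "Positive predictive value, % (95% CI)"),
    ("npv", "Negative predictive value, % (95% CI)"),
]


def render_table1(report: PerformanceReport) -> str:
    """Format a stratified performance report as the familiar three-column table."""
    order = [k for k in ("le", "gt", "overall") if k in report.strata]
    if set(order) != {"le", "gt", "overall"}:
        raise DataError("all three strata (le, gt, overall) are required")
    heads = {"le": "Age <=65 years", "gt": "Age >65 years", "overall": "Overall"}
    cols = {k: f"{heads[k]} (n={report.strata[k].table.total})" for k in order}
    lines = ["Result of screening algorithm\t" + "\t".join(cols[k] for k in order)]
    for attr, label in _ROW_LABELS:
        cells = [getattr(report.strata[k], attr).render() for k in order]
        lines.append(label + "\t" + "\t".join(cells))

    def prev_cells(get_pct, get_counts):
        out = []
        for k in order:
            pct, counts = get_pct(report.strata[k]), get_counts(report.strata[k])
            if pct is None or counts is None:
                out.append("-")
            else:
                out.append(f"{round_pct(pct):.1f} ({counts[0]}/{counts[1]})")
        return out

    lines.append("Disease prevalence (by ECG numbers), % (n/N)\t" + "\t".join(
        prev_cells(lambda s: s.prevalence_by_ecg_pct, lambda s: s.prevalence_by_ecg)))
    if all(report.strata[k].prevalence_by_subject is not None for k in order):
        lines.append("Disease prevalence (by screening resident numbers), % (n/N)\t"
                     + "\t".join(prev_cells(lambda s: s.prevalence_by_subject_pct,
                                            lambda s: s.prevalence_by_subject)))
    return "\n".join(lines)
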