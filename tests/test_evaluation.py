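"""Evaluation contracts: exact CIs, rates, confusion tables, the study table."""

import numpy as np
import pandas as pd
import pytest

from afscreen.errors import DataError, InvalidParameterError
from afscreen.evaluation import (ConfusionTable, build_confusion,
                                 exact_binomial_ci, predictive_value_ci, rates,
                                 reconstruct_study_table, recover_fp_from_ppv,
                                 render_table1, round_pct)


from cp_oracle import cp_bruteforce


class TestExactBinomialCI:
    @pytest.mark.parametrize("k,n,expected", [
        (21, 22, (77.2, 99.9)),
        (4, 4, (39.8, 100.0)),
        (921, 943, (96.5, 98.5)),
        (17, 18, (72.7, 99.9)),
        (406, 421, (94.2, 98.0)),
        (515, 522, (97.3, 99.5)),
    ])
    def test_printed_bounds(self, k, n, expected):
        lo, hi = exact_binomial_ci(k, n)
        assert (round_pct(lo), round_pct(hi)) == expected

    def test_zero_successes_lower_bound(self):
        lo, hi = exact_binomial_ci(0, 10)
        assert lo == 0.0

    def test_all_successes_upper_bound(self):
        assert exact_binomial_ci(10, 10)[1] == 100.0

    def test_invalid_counts(self):
        with pytest.raises(InvalidParameterError):
            exact_binomial_ci(5, 4)

    @pytest.mark.parametrize("n", [1, 4, 8, 12])
    def test_agrees_with_bruteforce_small_n(self, n):
        for k in range(n + 1):
            lo, hi = exact_binomial_ci(k, n)
            blo, bhi = cp_bruteforce(k, n)
            assert lo == pytest.approx(blo, abs=1e-6)
            assert hi == pytest.approx(bhi, abs=1e-6)

    def test_coverage_at_p09_n22(self):
        """95% CIs contain the true proportion in >= 93% of simulated draws."""
        rng = np.random.default_rng(12345)
        draws = rng.binomial(22, 0.9, size=2000)
        covered = sum(1 for k in draws
                      if exact_binomial_ci(int(k), 22)[0] <= 90.0 <= exact_binomial_ci(int(k), 22)[1])
        assert covered / 2000 >= 0.93


class TestPredictiveValueCI:
    @pytest.mark.parametrize("table,which,expected", [
        (ConfusionTable(21, 1, 22, 921), "ppv", (38.5, 59.3)),
        (ConfusionTable(21, 1, 22, 921), "npv", (99.3, 100.0)),
        (ConfusionTable(17, 1, 15, 406), "ppv", (40.5, 65.4)),
        (ConfusionTable(17, 1, 15, 406), "npv", (98.4, 100.0)),
        (ConfusionTable(4, 0, 7, 515), "ppv", (21.5, 54.4)),
    ])
    def test_printed_bounds(self, table, which, expected):
        lo, hi = predictive_value_ci(table, which)
        assert (round_pct(lo), round_pct(hi)) == expected

    def test_degenerate_npv_has_no_ci(self):
        # NPV = 515/515 = 100%: the logit interval is undefined at 1
        assert predictive_value_ci(ConfusionTable(4, 0, 7, 515), "npv") is None


class TestRates:
    def test_overall_study_counts(self):
        r = rates(ConfusionTable(21, 1, 22, 921))
        assert round_pct(r["sensitivity"]) == 95.5
        assert round_pct(r["specificity"]) == 97.7
        assert round_pct(r["ppv"]) == 48.8
        assert round_pct(r["npv"]) == 99.9
        assert round_pct(r["prevalence"]) == 2.3

    def test_elderly_stratum_counts(self):
        r = rates(ConfusionTable(17, 1, 15, 406))
        assert (round_pct(r["sensitivity"]), round_pct(r["specificity"]),
                round_pct(r["ppv"]), round_pct(r["npv"])) == (94.4, 96.4, 53.1, 99.8)

    def test_zero_denominator_is_none(self):
        r = rates(ConfusionTable(0, 0, 0, 10))
        assert r["sensitivity"] is None
        assert r["specificity"] == 100.0

    def test_round_half_up(self):
        assert round_pct(4.25) == 4.3
        assert round_pct(94.44444) == 94.4

    def test_bayes_consistency(self):
        """PPV from (sens, spec, prevalence) equals tp/(tp+fp) for each stratum."""
        for t in (ConfusionTable(4, 0, 7, 515), ConfusionTable(17, 1, 15, 406),
                  ConfusionTable(21, 1, 22, 921)):
            r = rates(t)
            se, sp, prev = (r["sensitivity"] / 100, r["specificity"] / 100,
                            r["prevalence"] / 100)
            ppv = 100 * se * prev / (se * prev + (1 - sp) * (1 - prev))
            assert ppv == pytest.approx(r["ppv"], abs=1e-9)


class TestBuildConfusion:
    def _frame(self):
        return pd.DataFrame({
            "call": ["AF", "NOT_AF", "AF", "NOT_AF", "UNGRADABLE", "NOT_AF"],
            "is_af": [True, True, False, False, True, False],
            "age": [70, 60, 70, 60, 70, 80],
            "grade": ["0", "1", "0", "2a", "3", "3"],
        })

    def test_strata_and_exclusion(self):
        conf = build_confusion(self._frame())
        ov = conf["overall"]
        # grade-3 and UNGRADABLE records are excluded before tabulation
        assert ov.total == 4
        assert (ov.tp, ov.fn, ov.fp, ov.tn) == (1, 1, 1, 1)
        assert conf["le"].total + conf["gt"].total == ov.total

    def test_empty_input(self):
        conf = build_confusion(pd.DataFrame({"call": [], "is_af": [], "age": []}))
        assert conf["overall"].total == 0

    def test_perfect_oracle_has_no_errors(self):
        df = self._frame()
        df["call"] = np.where(df["is_af"], "AF", "NOT_AF")
        conf = build_confusion(df)
        assert conf["overall"].fn == 0 and conf["overall"].fp == 0

    def test_missing_label_raises(self):
        df = self._frame()
        df["is_af"] = df["is_af"].astype(object)
        df.loc[0, "is_af"] = None
        with pytest.raises(DataError):
            build_confusion(df)


class TestStudyReconstruction:
    def test_confusion_closure(self):
        rep = reconstruct_study_table()
        ov = rep.strata["overall"].table
        assert (ov.tp, ov.fn, ov.fp, ov.tn) == (21, 1, 22, 921)
        assert ov.total == 965

    def test_recovered_stratum_fps_sum_to_printed_total(self):
        assert recover_fp_from_ppv(4, 36.4) == 7
        assert recover_fp_from_ppv(17, 53.1) == 15
        assert recover_fp_from_ppv(4, 36.4) + recover_fp_from_ppv(17, 53.1) == 22

    def test_stratum_additivity(self):
        rep = reconstruct_study_table()
        s = rep.strata["le"].table + rep.strata["gt"].table
        ov = rep.strata["overall"].table
        assert (s.tp, s.fn, s.fp, s.tn) == (ov.tp, ov.fn, ov.fp, ov.tn)

    def test_rendered_overall_column(self):
        text = render_table1(reconstruct_study_table())
        for cell in ("95.5 (95% CI 77.2%-99.9%)", "97.7 (95% CI 96.5%-98.5%)",
                     "48.8 (95% CI 38.5%-59.3%)", "99.9 (95% CI 99.3%-100.0%)"):
            assert cell in text

    def test_rendered_prevalence_rows(self):
        text = render_table1(reconstruct_study_table())
        assert "2.3 (22/965)" in text
        assert "2.4 (22/922)" in text
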