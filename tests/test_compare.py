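"""Method-comparison table, totals arithmetic and the statistical protocol.

The t-test and rank-sum implementations are cross-checked against explicit
brute-force arithmetic (pooled-variance formula, manual ranking) on the
packaged 12-sample reference table.
"""

import numpy as np
import pytest
from scipy import stats

from cocoonct.compare import (build_table, compare_methods, load_reference_counts,
                              normality_screen, rank_sum_test, render_report,
                              table_to_frame)
from cocoonct.postprocess import CountRecord

#: Per-sample VC rates as printed in the published per-sample table.
PRINTED_VC_RATES = [0.66, 0.37, 0.43, 0.43, 1.59, 0.34, 3.86, 1.45, 1.74, 0.58, 0.49, 1.83]
PRINTED_RC_RATES = [0.0, 0.36, 0.0, 0.36, 0.75, 0.33, 2.87, 1.15, 0.0, 0.0, 0.93, 1.06]


@pytest.fixture(scope="module")
def table():
    return load_reference_counts()


class TestTable:
    def test_vc_and_rc_and_ac_totals(self, table):
        assert (table.totals["VC"].healthy, table.totals["VC"].parasitoid) == (5864, 65)
        assert (table.totals["RC"].healthy, table.totals["RC"].parasitoid) == (3371, 21)
        assert (table.totals["AC"].healthy, table.totals["AC"].parasitoid) == (5855, 56)

    def test_totals_rates_recomputed_from_summed_counts(self, table):
        assert table.totals["VC"].parasitoid_rate_display == 1.11
        assert table.totals["RC"].parasitoid_rate_display == 0.62

    def test_per_sample_vc_and_rc_rates_match_printed_values(self, table):
        for i, sid in enumerate(table.sample_ids):
            assert table.records["VC"][sid].parasitoid_rate_display == PRINTED_VC_RATES[i]
            assert table.records["RC"][sid].parasitoid_rate_display == PRINTED_RC_RATES[i]

    def test_totals_are_exact_column_sums(self, table):
        for m in table.methods:
            assert table.totals[m].healthy == int(table.column(m, "healthy").sum())
            assert table.totals[m].parasitoid == int(table.column(m, "parasitoid").sum())

    def test_single_sample_single_method_totals_equal_row(self):
        t = build_table({"VC": [CountRecord(sample_id="s1", healthy=10, parasitoid=1)]})
        assert (t.totals["VC"].healthy, t.totals["VC"].parasitoid) == (10, 1)

    def test_mismatched_sample_sets_rejected(self):
        with pytest.raises(ValueError, match="sample sets differ"):
            build_table({"A": [CountRecord("s1", 1, 0)], "B": [CountRecord("s2", 1, 0)]})


class TestNormality:
    def test_healthy_columns_all_consistent_with_normality(self, table):
        reports = normality_screen({m: table.column(m, "healthy") for m in table.methods})
        assert len(reports) == 3
        for r in reports:
            assert r.test_name == "shapiro_wilk"
            assert r.p_value > 0.05

    def test_simulated_normal_samples_rarely_rejected(self):
        rejections = 0
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=50)
            (r,) = normality_screen({"x": x})
            rejections += r.p_value <= 0.001
        assert rejections <= 1

    def test_too_small_sample_is_an_error(self):
        with pytest.raises(ValueError, match="n >= 3"):
            normality_screen({"x": np.array([1.0, 2.0])})

    def test_constant_column_flagged_degenerate(self):
        (r,) = normality_screen({"x": np.ones(5)})
        assert r.degenerate


class TestComparisons:
    def test_rc_vs_vc_healthy_highly_significant(self, table):
        r = compare_methods(table, ("RC", "VC"), "healthy")
        assert r.test_name == "t_independent"
        assert r.p_value < 0.001

    def test_t_statistic_matches_pooled_variance_formula(self, table):
        a, b = table.column("RC", "healthy"), table.column("VC", "healthy")
        n1, n2 = len(a), len(b)
        sp2 = (((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2))
        t_brute = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        r = compare_methods(table, ("RC", "VC"), "healthy")
        assert r.statistic == pytest.approx(t_brute, rel=1e-12)

    def test_rank_sum_statistic_matches_manual_ranking(self, table):
        a = table.column("RC", "parasitoid")
        b = table.column("VC", "parasitoid")
        pooled = np.concatenate([a, b])
        # explicit average ranking
        order = np.argsort(pooled, kind="stable")
        ranks = np.empty(len(pooled))
        i = 0
        srt = pooled[order]
        while i < len(srt):
            j = i
            while j < len(srt) and srt[j] == srt[i]:
                j += 1
            ranks[order[i:j]] = np.mean(np.arange(i, j) + 1.0)
            i = j
        w_brute = ranks[:len(a)].sum()
        r = compare_methods(table, ("RC", "VC"), "parasitoid")
        assert r.statistic == pytest.approx(w_brute)

    def test_rank_sum_agrees_with_scipy_tie_corrected(self, table):
        a, b = table.column("RC", "rate"), table.column("VC", "rate")
        _, p = rank_sum_test(a, b, alternative="two_sided")
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        assert p == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_parasitoid_and_rate_show_rc_below_vc(self, table):
        for variable in ("parasitoid", "rate"):
            r = compare_methods(table, ("RC", "VC"), variable, alternative="less")
            assert r.test_name == "wilcoxon_rank_sum"
            assert r.p_value < 0.05

    def test_identical_columns_give_p_one(self, table):
        t = build_table({"A": [CountRecord(str(i), 10 + i, i) for i in range(6)],
                         "B": [CountRecord(str(i), 10 + i, i) for i in range(6)]})
        r = compare_methods(t, ("A", "B"), "parasitoid")
        assert r.p_value == pytest.approx(1.0)

    def test_exact_rank_sum_reproduces_published_one_sided_p_values(self, table):
        _, p_count = rank_sum_test(table.column("RC", "parasitoid"),
                                   table.column("VC", "parasitoid"),
                                   alternative="less", exact=True)
        _, p_rate = rank_sum_test(table.column("RC", "rate"),
                                  table.column("VC", "rate"),
                                  alternative="less", exact=True)
        assert round(p_count, 3) == 0.004
        assert round(p_rate, 3) == 0.039

    def test_unknown_variable_rejected(self, table):
        with pytest.raises(ValueError, match="unknown variable"):
            compare_methods(table, ("RC", "VC"), "weight")


class TestReportRendering:
    def test_total_row_lists_all_method_totals(self, table, tmp_path):
        text = render_report(table, [], out_csv=tmp_path / "report.csv")
        total_line = [l for l in text.splitlines() if l.startswith("Total")][0]
        for v in ("3371", "5864", "5855", "21", "65", "56"):
            assert v in total_line.split(",")

    def test_rerender_is_byte_identical(self, table, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        render_report(table, [], out_csv=p1)
        render_report(table, [], out_csv=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_reports_give_table_only(self, table):
        text = render_report(table, [])
        assert "statistical tests" not in text

    def test_frame_has_sample_rows_plus_total(self, table):
        frame = table_to_frame(table)
        assert len(frame) == 13
        assert frame.iloc[-1]["sample_id"] == "Total"
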