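"""ROR/IC estimators, signal criterion, screening and SOC frequency tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerspv.cohorts import Group
from faerspv.disproportionality import (
    ContingencyTable,
    ZeroCellError,
    build_contingency,
    compute_ic,
    compute_ror,
    flag_signal,
    frequency_percentages,
    screen_all_terms,
    soc_frequency_table,
)

from conftest import make_report

cells = st.integers(1, 10_000)


class TestComputeRor:
    def test_worked_example(self):
        ror, lo, hi = compute_ror(ContingencyTable(5, 95, 10, 890))
        # full-precision formula evaluation: 4.68421..., (1.56834, 13.9907)
        assert ror == pytest.approx(4.684, abs=5e-4)
        assert lo == pytest.approx(1.5683, abs=5e-4)
        assert hi == pytest.approx(13.991, abs=5e-3)

    @pytest.mark.parametrize("n", [1, 7, 100])
    def test_symmetric_table_is_null(self, n):
        ror, lo, hi = compute_ror(ContingencyTable(n, n, n, n))
        assert ror == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_zero_cell_raises_without_correction(self):
        with pytest.raises(ZeroCellError, match="nausea"):
            compute_ror(ContingencyTable(0, 10, 5, 100), term="nausea")

    def test_haldane_correction_handles_zero_cell(self):
        ror, lo, hi = compute_ror(ContingencyTable(0, 10, 5, 100), correction=True)
        expected = (0.5 * 100.5) / (10.5 * 5.5)
        assert ror == pytest.approx(expected)
        assert lo < ror < hi

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(deadline=None, max_examples=300)
    def test_matches_full_precision_oracle(self, a, b, c, d):
        """ROR and Woolf CI agree with direct formula evaluation to 1e-12."""
        ror, lo, hi = compute_ror(ContingencyTable(a, b, c, d))
        oror = (a * d) / (b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert ror == pytest.approx(oror, rel=1e-12)
        assert lo == pytest.approx(oror * math.exp(-1.96 * se), rel=1e-12)
        assert hi == pytest.approx(oror * math.exp(1.96 * se), rel=1e-12)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(deadline=None, max_examples=100)
    def test_group_swap_reciprocal(self, a, b, c, d):
        """Swapping index and comparator rows inverts the ROR."""
        ror, lo, hi = compute_ror(ContingencyTable(a, b, c, d))
        swapped, slo, shi = compute_ror(ContingencyTable(c, d, a, b))
        assert swapped == pytest.approx(1.0 / ror, rel=1e-10)
        assert slo == pytest.approx(1.0 / hi, rel=1e-10)
        assert shi == pytest.approx(1.0 / lo, rel=1e-10)

    def test_against_statsmodels_odds_ratio(self):
        """Cross-check against the independent 2x2 implementation."""
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        from scipy.stats import norm

        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 500, size=4)
            table = sm.Table2x2([[a, b], [c, d]])
            # exact normal quantile here; the library default is the
            # conventional printed 1.96
            ror, lo, hi = compute_ror(ContingencyTable(a, b, c, d), z=norm.ppf(0.975))
            assert ror == pytest.approx(table.oddsratio, rel=1e-12)
            slo, shi = table.oddsratio_confint(0.05)
            assert lo == pytest.approx(slo, rel=1e-6)
            assert hi == pytest.approx(shi, rel=1e-6)


class TestComputeIc:
    def test_worked_shrinkage_example(self):
        # a=5, index size 100, event margin 15, N=1000
        ic, ic025 = compute_ic(ContingencyTable(5, 95, 10, 890))
        assert ic == pytest.approx(1.459, abs=5e-4)
        assert ic025 == pytest.approx(-0.103, abs=5e-4)

    @pytest.mark.parametrize("n", [1, 4, 250])
    def test_independent_table_gives_zero(self, n):
        ic, _ = compute_ic(ContingencyTable(n, n, n, n))
        assert ic == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_observed_count(self):
        ic1, _ = compute_ic(ContingencyTable(5, 95, 10, 890))
        ic2, _ = compute_ic(ContingencyTable(10, 90, 10, 890))
        assert ic2 > ic1

    @given(a=st.integers(1, 2000), b=st.integers(1, 2000), c=st.integers(1, 2000), d=st.integers(1, 2000))
    @settings(deadline=None, max_examples=200)
    def test_shrinkage_pulls_toward_zero(self, a, b, c, d):
        """|IC| never exceeds the unshrunk log2(observed/expected)."""
        t = ContingencyTable(a, b, c, d)
        e11 = (a + b) * (a + c) / t.n
        if e11 < 1 or a == pytest.approx(e11):
            return
        raw = math.log2(a / e11)
        ic, _ = compute_ic(t)
        assert abs(ic) <= abs(raw) + 1e-12

    def test_ic025_below_ic(self):
        ic, ic025 = compute_ic(ContingencyTable(50, 450, 20, 480))
        assert ic025 < ic


class TestFlagSignal:
    @pytest.mark.parametrize(
        "ror, ic, ic025",
        [(189.94, 3.37, 1.59), (99.46, 3.31, 1.44), (69.5, 3.25, 1.33)],
    )
    def test_published_top_signals_flagged(self, ror, ic, ic025):
        assert flag_signal(ror, ic, ic025)

    @pytest.mark.parametrize(
        "ror, ic, ic025, expected",
        [
            (1.0, 3.0, 1.0, False),  # boundary excluded
            (5.0, 0.4, -0.1, False),  # IC025 rule
            (5.0, -0.1, 0.1, False),
            (1.0001, 0.001, 0.0001, True),
        ],
    )
    def test_strict_criterion(self, ror, ic, ic025, expected):
        assert flag_signal(ror, ic, ic025) is expected


def _cohort(index_pts, comparator_pts):
    """Build (assignments, reports) with given per-report PT lists."""
    from faerspv.cohorts import build_cohort

    reports = []
    for i, pts in enumerate(index_pts):
        reports.append(
            make_report(
                primaryid=f"i{i}", caseid=f"i{i}", reaction_pts=pts,
                drugs=[("PEMBROLIZUMAB", "PS", "breast cancer"), ("PACLITAXEL", "C")],
            )
        )
    for i, pts in enumerate(comparator_pts):
        reports.append(
            make_report(
                primaryid=f"c{i}", caseid=f"c{i}", reaction_pts=pts,
                drugs=[("PACLITAXEL", "PS", "breast cancer")],
            )
        )
    return build_cohort(reports), reports


class TestBuildContingency:
    def test_direct_count(self):
        assignments, reports = _cohort([["x"], []], [["x"]])
        t = build_contingency(assignments, reports, "x")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 0)

    def test_repeated_pt_counts_once(self):
        assignments, reports = _cohort([["x", "x"]], [[]])
        t = build_contingency(assignments, reports, "x")
        assert t.a == 1

    def test_hand_counted_cohort(self):
        index = [["x"]] * 3 + [[]] * 7
        comp = [["x"]] * 2 + [[]] * 18
        assignments, reports = _cohort(index, comp)
        t = build_contingency(assignments, reports, "x")
        assert (t.a, t.b, t.c, t.d) == (3, 7, 2, 18)

    def test_same_group_rejected(self):
        assignments, reports = _cohort([["x"]], [["x"]])
        with pytest.raises(ValueError, match="overlap"):
            build_contingency(
                assignments, reports, "x",
                index_group=Group.COMBINATION, comparator_group=Group.COMBINATION,
            )


class TestScreenAllTerms:
    def test_injected_term_ranks_first(self):
        index = [["bad", "common"]] * 6 + [["common"]] * 2 + [[]] * 2
        comp = [["common"]] * 8 + [["bad"]] * 1 + [[]] * 1
        assignments, reports = _cohort(index, comp)
        results = screen_all_terms(assignments, reports, min_count=1)
        assert results[0].event_term == "bad"

    def test_min_count_filters(self):
        index = [["rare"]] * 2 + [["common"]] * 5 + [[]] * 3
        comp = [["rare"], ["common"], [], []]
        assignments, reports = _cohort(index, comp)
        terms = {r.event_term for r in screen_all_terms(assignments, reports, min_count=3)}
        assert "rare" not in terms and "common" in terms

    def test_tie_break_larger_a_first(self):
        # two terms with identical ROR; the one with more index reports leads
        index = [["x", "y"], ["x", "y"], ["x"], ["y"]] + [[]] * 4
        comp = [["x"], ["y"], [], []]
        assignments, reports = _cohort(index, comp)
        results = screen_all_terms(assignments, reports, min_count=1)
        rors = [r.ror for r in results]
        assert rors == sorted(rors, reverse=True)
        equal = [r for r in results if r.ror == pytest.approx(results[0].ror)]
        a_counts = [r.table.a for r in equal]
        assert a_counts == sorted(a_counts, reverse=True)

    def test_zero_cell_error_lists_terms(self):
        assignments, reports = _cohort([["only here"]] * 3, [[]] * 3)
        with pytest.raises(ZeroCellError, match="only here"):
            screen_all_terms(assignments, reports, min_count=1)
        results = screen_all_terms(assignments, reports, min_count=1, correction=True)
        assert results[0].event_term == "only here"


class TestSocFrequency:
    PT_SOC = {"x": "SOC One", "y": "SOC One", "z": "SOC Two"}

    def test_single_report_single_pt(self):
        assignments, reports = _cohort([["x"]], [[]])
        table = soc_frequency_table(assignments, reports, self.PT_SOC)
        assert table.loc["SOC One", ("count", "combination")] == 1
        assert table.loc["SOC One", ("pct", "combination")] == pytest.approx(100.0)

    def test_event_level_counting(self):
        # one report with two PTs in the same SOC contributes two events
        assignments, reports = _cohort([["x", "y", "z"]], [["x"]])
        table = soc_frequency_table(assignments, reports, self.PT_SOC)
        assert table.loc["SOC One", ("count", "combination")] == 2
        assert table.loc["SOC Two", ("count", "combination")] == 1

    def test_percentages_normalize_and_counts_conserve(self):
        assignments, reports = _cohort(
            [["x", "y"], ["z"], ["x"]], [["x"], ["z", "unknown pt"]]
        )
        table = soc_frequency_table(assignments, reports, self.PT_SOC)
        for col in table["pct"].columns:
            if table["count"][col].sum():
                assert table["pct"][col].sum() == pytest.approx(100.0, abs=0.05)
        total_events = sum(
            len(set(r.reaction_pts)) for r in reports
        )
        assert table["count"]["Total"].sum() == total_events
        assert "unmapped" in table.index

    def test_frequency_percentages_helper(self):
        counts = pd.DataFrame({"g": [224, 1571]}, index=["A", "B"])
        pct = frequency_percentages(counts)
        assert pct.loc["A", "g"] == pytest.approx(100 * 224 / 1795)
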