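"""Wald intervals, interval overlap, frequency matching, concordance."""

from datetime import date

import pandas as pd
import pytest

from forumrx.compare import (ProportionEstimate, compare_sources,
                             concordance_report, frequency_match, overlap,
                             proportion_table, wald_halfwidth_pct)


class TestWald:
    def test_large_cohort_half_width(self):
        assert round(wald_halfwidth_pct(0.422, 817), 1) == 3.4

    def test_degenerate_proportion(self):
        assert wald_halfwidth_pct(0.0, 500) == 0.0
        assert wald_halfwidth_pct(1.0, 500) == 0.0

    def test_closed_form_half(self):
        assert round(wald_halfwidth_pct(0.5, 100), 1) == 9.8

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wald_halfwidth_pct(1.2, 10)
        with pytest.raises(ValueError):
            wald_halfwidth_pct(0.5, 0)


def _est(prop, hw, source="s", line=1, regimen="r"):
    return ProportionEstimate(source, line, regimen, 0, 1, prop, hw)


class TestOverlap:
    def test_clear_overlap(self):
        assert overlap(_est(42.2, 3.4), _est(45.2, 4.1, "db"))

    def test_clear_separation(self):
        assert not overlap(_est(42.2, 3.4), _est(24.8, 1.6, "db"))

    def test_touching_endpoints_count(self):
        assert overlap(_est(6.0, 1.6), _est(9.7, 2.1, "db"))  # both hit 7.6

    def test_mismatched_rows_rejected(self):
        with pytest.raises(ValueError):
            overlap(_est(10, 1, line=1), _est(10, 1, "db", line=2))


def _pool(counts, database="dbA"):
    rows = []
    for year, n in counts.items():
        for i in range(n):
            rows.append((f"{database}-{year}-{i}", database, year, 1,
                         "ipilimumab", date(year, 6, 15)))
    return pd.DataFrame(rows, columns=["patient_id", "database",
                                       "first_line_year", "line_number",
                                       "regimen", "start_date"])


class TestFrequencyMatch:
    def test_ample_pool_takes_four_per_index_patient(self):
        cohort = frequency_match({2013: 140}, _pool({2013: 600}), ratio=4, seed=0)
        assert cohort.matched_counts[2013] == 560

    def test_scarce_pool_capped_at_pool_size(self):
        cohort = frequency_match({2011: 40}, _pool({2011: 104}), ratio=4, seed=0)
        assert cohort.matched_counts[2011] == 104

    def test_empty_pool_year_drops_index_patients(self):
        cohort = frequency_match({2014: 3}, _pool({2013: 10}), ratio=4, seed=0)
        assert cohort.matched_counts[2014] == 0
        assert len(cohort.dropped_sm) == 3

    def test_same_seed_identical_selection(self):
        pool = _pool({2013: 600})
        a = frequency_match({2013: 100}, pool, seed=42)
        b = frequency_match({2013: 100}, pool, seed=42)
        assert a.patients.equals(b.patients)

    def test_counts_invariant_to_seed(self):
        pool = _pool({2013: 600, 2014: 50})
        a = frequency_match({2013: 100, 2014: 100}, pool, seed=1)
        b = frequency_match({2013: 100, 2014: 100}, pool, seed=2)
        assert a.matched_counts == b.matched_counts
        assert not a.patients.equals(b.patients)

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            frequency_match({2013: 1}, _pool({2013: 5}), ratio=0)


def _lines(rows):
    return pd.DataFrame(rows, columns=["patient_id", "line_number", "regimen",
                                       "start_date"])


class TestProportionTable:
    def test_counts_and_denominator(self):
        table = _lines([
            ("a", 1, "ipilimumab", date(2014, 1, 15)),
            ("b", 1, "ipilimumab", date(2014, 2, 15)),
            ("c", 1, "nivolumab", date(2014, 3, 15)),
            ("a", 2, "nivolumab", date(2014, 9, 15)),
        ])
        (est,) = proportion_table(table, 1, regimens=["ipilimumab"], source="x")
        assert (est.numerator, est.denominator) == (2, 3)
        assert est.proportion == 66.7

    def test_zero_denominator_rejected(self):
        table = _lines([("a", 1, "ipilimumab", date(2014, 1, 15))])
        with pytest.raises(ValueError):
            proportion_table(table, 3)


class TestConcordance:
    def test_no_databases_no_flags(self):
        sm = _lines([("a", 1, "ipilimumab", date(2014, 1, 15))])
        rows = compare_sources(sm, {}, 1, top_k=3)
        assert rows[0].overlap_flags == {}
        assert not rows[0].any_overlap

    def test_identical_sources_always_overlap(self):
        sm = _lines([("a", 1, "ipilimumab", date(2014, 1, 15)),
                     ("b", 1, "nivolumab", date(2014, 1, 15))])
        rows = compare_sources(sm, {"db": sm.copy()}, 1, top_k=2)
        assert all(r.any_overlap for r in rows)
        report = concordance_report(rows)
        assert report["per_line"][1]["fraction_any_overlap"] == 1.0
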