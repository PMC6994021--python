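"""Timeline construction and line-of-therapy assignment rules."""

from datetime import date

import pandas as pd
import pytest

from forumrx.lines import (PatientTimeline, assign_lines, build_timeline,
                           line_counts, lines_table)


def _resolved(events, user_id="u1"):
    return pd.DataFrame(
        [{"user_id": user_id, "canonical": drug, "event_date": d}
         for d, drug in events]
    )


def _timeline(events, user_id="u1"):
    return PatientTimeline(user_id, tuple(sorted(events)))


class TestBuildTimeline:
    def test_same_month_remention_collapsed(self):
        tl = build_timeline(_resolved([
            (date(2014, 3, 2), "ipilimumab"),
            (date(2014, 3, 15), "ipilimumab"),
            (date(2014, 3, 28), "ipilimumab"),
        ]))
        assert tl.events == ((date(2014, 3, 2), "ipilimumab"),)

    def test_empty(self):
        assert build_timeline(_resolved([])).events == ()

    def test_same_date_ties_alphabetical(self):
        tl = build_timeline(_resolved([
            (date(2014, 3, 15), "nivolumab"),
            (date(2014, 3, 15), "ipilimumab"),
        ]))
        assert [d for _, d in tl.events] == ["ipilimumab", "nivolumab"]

    def test_mixed_users_rejected(self):
        frame = pd.concat([_resolved([(date(2014, 3, 1), "ipilimumab")], "a"),
                           _resolved([(date(2014, 4, 1), "nivolumab")], "b")])
        with pytest.raises(ValueError):
            build_timeline(frame)


class TestAssignLines:
    def test_adjuvant_monotherapy_is_not_a_line(self):
        lines = assign_lines(_timeline([(date(2013, 1, 15), "interferon")]))
        assert lines == []

    def test_same_day_combination_single_line(self):
        lines = assign_lines(_timeline([
            (date(2014, 3, 15), "ipilimumab"),
            (date(2014, 3, 15), "nivolumab"),
        ]))
        assert len(lines) == 1
        assert lines[0].regimen == {"ipilimumab", "nivolumab"}

    def test_window_groups_and_new_drug_advances(self):
        lines = assign_lines(_timeline([
            (date(2014, 3, 15), "ipilimumab"),
            (date(2014, 9, 15), "dabrafenib"),
            (date(2014, 9, 15), "trametinib"),
        ]))
        assert [(l.line_number, set(l.regimen)) for l in lines] == [
            (1, {"ipilimumab"}), (2, {"dabrafenib", "trametinib"})]

    def test_adjuvant_joins_genuine_combination_window(self):
        lines = assign_lines(_timeline([
            (date(2014, 3, 15), "ipilimumab"),
            (date(2014, 3, 25), "interferon"),
        ]))
        assert lines[0].regimen == {"ipilimumab", "interferon"}

    def test_discarded_adjuvant_does_not_consume_a_line_number(self):
        lines = assign_lines(_timeline([
            (date(2013, 1, 15), "interferon"),
            (date(2014, 3, 15), "ipilimumab"),
        ]))
        assert [(l.line_number, set(l.regimen)) for l in lines] == [
            (1, {"ipilimumab"})]

    def test_previous_drug_carried_into_same_day_combination(self):
        lines = assign_lines(_timeline([
            (date(2014, 3, 15), "ipilimumab"),
            (date(2015, 1, 15), "ipilimumab"),
            (date(2015, 1, 15), "nivolumab"),
        ]))
        assert [(l.line_number, set(l.regimen)) for l in lines] == [
            (1, {"ipilimumab"}), (2, {"ipilimumab", "nivolumab"})]

    def test_remention_never_advances_lines(self):
        lines = assign_lines(_timeline([
            (date(2014, 3, 15), "ipilimumab"),
            (date(2014, 8, 15), "ipilimumab"),
        ]))
        assert len(lines) == 1

    def test_input_order_irrelevant(self):
        events = [(date(2014, 3, 15), "ipilimumab"),
                  (date(2014, 9, 15), "nivolumab"),
                  (date(2015, 6, 15), "pembrolizumab")]
        frames = [_resolved(events), _resolved(events[::-1])]
        results = [assign_lines(build_timeline(f)) for f in frames]
        assert results[0] == results[1]

    def test_adding_later_drug_never_decreases_lines(self):
        base = [(date(2014, 3, 15), "ipilimumab"),
                (date(2014, 9, 15), "nivolumab")]
        extended = base + [(date(2015, 6, 15), "pembrolizumab")]
        assert len(assign_lines(_timeline(extended))) >= len(
            assign_lines(_timeline(base)))


class TestLineCounts:
    def _cohort(self, n1, n2, n3):
        rows = []
        for i in range(n1):
            rows.append((f"p{i}", 1, "ipilimumab", date(2014, 1, 15)))
            if i < n2:
                rows.append((f"p{i}", 2, "nivolumab", date(2014, 8, 15)))
            if i < n3:
                rows.append((f"p{i}", 3, "pembrolizumab", date(2015, 3, 15)))
        return pd.DataFrame(
            rows, columns=["patient_id", "line_number", "regimen", "start_date"])

    def test_retention_percentages_one_decimal(self):
        counts = line_counts(self._cohort(817, 226, 73))
        assert list(counts["n_patients"]) == [817, 226, 73]
        assert list(counts["pct_of_first_line"]) == [100.0, 27.7, 8.9]

    def test_zero_patients(self):
        counts = line_counts(self._cohort(0, 0, 0))
        assert list(counts["n_patients"]) == [0, 0, 0]
        assert counts["pct_of_first_line"].isna().all()


def test_lines_table_multi_patient_schema():
    frame = pd.concat([
        _resolved([(date(2014, 3, 15), "ipilimumab")], "a"),
        _resolved([(date(2013, 1, 15), "interferon")], "b"),
    ])
    table = lines_table(frame)
    assert list(table.columns) == ["patient_id", "line_number", "regimen",
                                   "start_date"]
    assert set(table["patient_id"]) == {"a"}  # adjuvant-only patient has no lines
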