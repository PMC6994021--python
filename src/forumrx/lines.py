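"""Per-patient treatment timelines and line-of-therapy derivation.

The line algorithm is explicit and testable:

1. the first non-adjuvant event opens line 1;
2. a drug whose first event falls within ``combo_window_days`` of the current
   line's start joins that line's regimen (combination therapy);
3. a new drug (not in the current regimen) appearing after the window closes
   the current line and opens the next;
4. re-mentions of drugs already in the current regimen never advance lines,
   but a same-day event alongside a line-opening new drug carries the drug
   into the new combination (ipilimumab -> ipilimumab+nivolumab);
5. a line whose regimen would be exactly {interferon} or {docetaxel} is
   discarded — those agents are adjuvant when given alone;
6. interferon/docetaxel arriving inside a multi-drug combination window do
   count as members of that regimen.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import pandas as pd

__all__ = [
    "DEFAULT_COMBO_WINDOW_DAYS",
    "ADJUVANT_DRUGS",
    "PatientTimeline",
    "TherapyLine",
    "build_timeline",
    "assign_lines",
    "lines_table",
    "line_counts",
    "regimen_label",
]

DEFAULT_COMBO_WINDOW_DAYS = 28

#: Drugs never counted as a line when received as monotherapy.
ADJUVANT_DRUGS = frozenset({"interferon", "docetaxel"})


@dataclass(frozen=True)
class PatientTimeline:
    """Chronological, de-duplicated (event_date, drug) events of one patient."""

    user_id: str
    events: tuple[tuple[date, str], ...]


@dataclass(frozen=True)
class TherapyLine:
    patient_id: str
    line_number: int
    regimen: frozenset[str]
    start_date: date


def regimen_label(regimen) -> str:
    """Canonical comparison label: sorted canonical names joined by '+'."""
    return "+".join(sorted(regimen))


def build_timeline(resolved: pd.DataFrame, user_id: str | None = None) -> PatientTimeline:
    """Collapse resolved mentions of one patient into a sorted event list.

    Events are de-duplicated at (drug, calendar month) granularity, keeping
    the earliest date seen in that month; ties on the same date order
    alphabetically by drug so the result is independent of input order.
    """
    if resolved.empty:
        return PatientTimeline(user_id or "", ())
    users = set(resolved["user_id"])
    if len(users) > 1:
        raise ValueError(f"mixed user_ids in one timeline: {sorted(users)}")
    uid = user_id or next(iter(users))
    earliest: dict[tuple[str, int, int], date] = {}
    for row in resolved.itertuples():
        d = row.event_date
        key = (row.canonical, d.year, d.month)
        if key not in earliest or d < earliest[key]:
            earliest[key] = d
    events = sorted((d, drug) for (drug, _, _), d in earliest.items())
    return PatientTimeline(uid, tuple(events))


def assign_lines(
    timeline: PatientTimeline,
    combo_window_days: int = DEFAULT_COMBO_WINDOW_DAYS,
    adjuvant_drugs: frozenset[str] = ADJUVANT_DRUGS,
) -> list[TherapyLine]:
    """Derive numbered lines of therapy from a patient timeline.

    Lines are built greedily (rules 1-4 above), then adjuvant-monotherapy
    lines are discarded (rule 5) and the remainder renumbered consecutively.
    Building before filtering is what lets an adjuvant drug join a genuine
    combination window (rule 6).
    """
    raw: list[tuple[date, set[str]]] = []
    by_date: dict[date, list[str]] = {}
    for event_date, drug in timeline.events:
        by_date.setdefault(event_date, []).append(drug)
    for event_date in sorted(by_date):
        day_drugs = by_date[event_date]
        for drug in day_drugs:
            if raw:
                start, regimen = raw[-1]
                if drug in regimen:
                    continue
                if (event_date - start).days <= combo_window_days:
                    regimen.add(drug)
                    continue
                # a new line opens; same-day events of drugs carried over from
                # the previous regimen belong to the new combination, not to a
                # re-mention of the old line
                carried = {x for x in day_drugs if x in regimen}
            else:
                carried = set()
            raw.append((event_date, {drug} | carried))
    lines = []
    number = 0
    for start, regimen in raw:
        if len(regimen) == 1 and next(iter(regimen)) in adjuvant_drugs:
            continue
        number += 1
        lines.append(
            TherapyLine(timeline.user_id, number, frozenset(regimen), start)
        )
    return lines


def lines_table(
    resolved: pd.DataFrame,
    combo_window_days: int = DEFAULT_COMBO_WINDOW_DAYS,
) -> pd.DataFrame:
    """Resolved mentions (any number of patients) -> line-of-therapy table.

    Columns: patient_id, line_number, regimen ('+'-joined sorted canonical
    names), start_date. The same schema is used for comparator cohorts, so
    downstream comparison code is source-agnostic.
    """
    rows = []
    if not resolved.empty:
        for uid, group in resolved.groupby("user_id", sort=True):
            for line in assign_lines(build_timeline(group, uid), combo_window_days):
                rows.append(
                    (line.patient_id, line.line_number,
                     regimen_label(line.regimen), line.start_date)
                )
    return pd.DataFrame(
        rows, columns=["patient_id", "line_number", "regimen", "start_date"]
    )


def line_counts(lines: pd.DataFrame, max_line: int = 3) -> pd.DataFrame:
    """Patients with data at each treatment line.

    Counts patients with >= 1, >= 2, ... lines; percentages are relative to
    the first-line count, rounded to one decimal. With zero patients all
    counts are 0 and percentages are absent (NaN).
    """
    per_patient = (
        lines.groupby("patient_id")["line_number"].max()
        if not lines.empty
        else pd.Series(dtype=int)
    )
    rows = []
    first = int((per_patient >= 1).sum())
    for k in range(1, max_line + 1):
        n = int((per_patient >= k).sum())
        pct = round(100.0 * n / first, 1) if first else float("nan")
        rows.append((k, n, pct))
    return pd.DataFrame(rows, columns=["line_number", "n_patients", "pct_of_first_line"])
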