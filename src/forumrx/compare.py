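"""Frequency matching, Wald proportion estimates, and CI-overlap concordance.

Comparator patients are frequency-matched 4:1 to the social-media cohort on
first-line initiation year; per-line regimen proportions carry Wald 95%
intervals (p-hat +/- 1.96*sqrt(p(1-p)/n), which can extend below zero for
small p-hat); two estimates are called concordant when their reported
(rounded) closed intervals intersect — touching endpoints count as overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Z95",
    "wald_halfwidth_pct",
    "ProportionEstimate",
    "ComparisonRow",
    "MatchedCohort",
    "frequency_match",
    "proportion_table",
    "overlap",
    "compare_sources",
    "concordance_report",
]

Z95 = 1.96


def wald_halfwidth_pct(p_hat: float, n: int) -> float:
    """Wald 95% half-width in percentage points, from an unrounded p-hat."""
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError(f"p_hat out of [0, 1]: {p_hat}")
    if n <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * Z95 * math.sqrt(p_hat * (1.0 - p_hat) / n)


@dataclass(frozen=True)
class ProportionEstimate:
    """A per-line regimen proportion (%) with its 95% CI half-width (%).

    ``proportion`` and ``ci_half_width`` are reported rounded to one decimal,
    the precision at which estimates are compared; the integer numerator and
    denominator retain full information.
    """

    source: str
    line_number: int
    regimen: str
    numerator: int
    denominator: int
    proportion: float
    ci_half_width: float

    @classmethod
    def from_counts(cls, source, line_number, regimen, numerator, denominator):
        if denominator <= 0:
            raise ValueError(f"zero denominator for {source} line {line_number}")
        p_hat = numerator / denominator
        return cls(
            source=source,
            line_number=line_number,
            regimen=regimen,
            numerator=int(numerator),
            denominator=int(denominator),
            proportion=round(100.0 * p_hat, 1),
            ci_half_width=round(wald_halfwidth_pct(p_hat, denominator), 1),
        )

    @property
    def interval(self) -> tuple[float, float]:
        return (self.proportion - self.ci_half_width,
                self.proportion + self.ci_half_width)


def overlap(a: ProportionEstimate, b: ProportionEstimate) -> bool:
    """Closed-interval intersection of the reported (rounded) intervals."""
    if (a.line_number, a.regimen) != (b.line_number, b.regimen):
        raise ValueError(
            f"cannot compare {a.source} line {a.line_number} {a.regimen!r} "
            f"with {b.source} line {b.line_number} {b.regimen!r}"
        )
    a_lo, a_hi = a.interval
    b_lo, b_hi = b.interval
    return a_lo <= b_hi and b_lo <= a_hi


@dataclass(frozen=True)
class ComparisonRow:
    """One regimen at one line: estimates per source and overlap verdicts of
    the social-media interval against each database interval."""

    line_number: int
    regimen: str
    estimates: dict[str, ProportionEstimate]
    overlap_flags: dict[str, bool]

    @property
    def any_overlap(self) -> bool:
        return any(self.overlap_flags.values())


@dataclass
class MatchedCohort:
    """Result of frequency matching one comparator database."""

    database: str
    patients: pd.DataFrame  # line-table rows of the retained patients
    matched_counts: dict[int, int]
    dropped_sm: list = field(default_factory=list)  # unmatched social-media ids/years

    @property
    def total_matched(self) -> int:
        return sum(self.matched_counts.values())


def _sm_year_ids(sm_years) -> dict[int, list]:
    """Accept {year: count} or {year: [patient ids]}; normalize to id lists."""
    out = {}
    for year, val in sm_years.items():
        if isinstance(val, (int, np.integer)):
            out[int(year)] = [f"sm-{year}-{i}" for i in range(int(val))]
        else:
            out[int(year)] = list(val)
    return out


def frequency_match(
    sm_years,
    pool: pd.DataFrame,
    ratio: int = 4,
    seed: int = 0,
    database: str | None = None,
) -> MatchedCohort:
    """Frequency-match comparator patients to the social-media cohort.

    For each first-line year y, ``min(pool_count(y), ratio * sm_count(y))``
    comparator patients are selected uniformly at random (seeded). Social-media
    patients in years with an empty pool cannot be matched and are reported
    dropped.

    ``sm_years`` is a mapping year -> count (or year -> list of patient ids);
    ``pool`` is a line table with at least patient_id and first_line_year
    columns (a ``database`` column is used when ``database`` is not given).
    """
    if ratio < 1:
        raise ValueError("matching ratio must be >= 1")
    if database is None:
        dbs = set(pool["database"]) if "database" in pool.columns else {""}
        if len(dbs) != 1:
            raise ValueError("pool holds several databases; pass database=...")
        database = next(iter(dbs))
    elif "database" in pool.columns:
        pool = pool[pool["database"] == database]

    sm_ids = _sm_year_ids(sm_years)
    years_of = (
        pool.drop_duplicates("patient_id").set_index("patient_id")["first_line_year"]
    )
    rng = np.random.default_rng(seed)
    matched_counts: dict[int, int] = {}
    dropped: list = []
    chosen: list = []
    for year in sorted(sm_ids):
        ids = sorted(years_of.index[years_of == year])
        take = min(len(ids), ratio * len(sm_ids[year]))
        matched_counts[year] = take
        if ids and take:
            chosen.extend(rng.choice(ids, size=take, replace=False))
        if not ids:
            dropped.extend(sm_ids[year])
    patients = pool[pool["patient_id"].isin(set(chosen))].reset_index(drop=True)
    return MatchedCohort(database, patients, matched_counts, dropped)


def proportion_table(
    lines: pd.DataFrame,
    line_number: int,
    regimens: list[str] | None = None,
    top_k: int | None = None,
    source: str = "",
) -> list[ProportionEstimate]:
    """Per-regimen proportion estimates at one treatment line.

    The denominator is the number of patients with >= ``line_number`` lines;
    the numerator counts patients whose line-N regimen equals the label.
    ``regimens`` fixes the rows (for cross-source comparison); otherwise the
    ``top_k`` most frequent regimens at that line are reported.
    """
    per_patient = lines.groupby("patient_id")["line_number"].max()
    denominator = int((per_patient >= line_number).sum())
    if denominator == 0:
        raise ValueError(f"no patients with line {line_number} in {source or 'cohort'}")
    at_line = lines[lines["line_number"] == line_number]
    counts = at_line["regimen"].value_counts()
    if regimens is None:
        regimens = list(counts.index[: (top_k or len(counts))])
    return [
        ProportionEstimate.from_counts(
            source, line_number, reg, int(counts.get(reg, 0)), denominator
        )
        for reg in regimens
    ]


def compare_sources(
    sm_lines: pd.DataFrame,
    db_lines: dict[str, pd.DataFrame],
    line_number: int,
    regimens: list[str] | None = None,
    top_k: int = 6,
    sm_name: str = "social_media",
) -> list[ComparisonRow]:
    """Build the per-regimen comparison grid for one treatment line.

    Rows default to the social-media cohort's ``top_k`` regimens at that line.
    """
    sm_estimates = proportion_table(
        sm_lines, line_number, regimens=regimens, top_k=top_k, source=sm_name
    )
    row_regimens = [e.regimen for e in sm_estimates]
    rows = []
    for sm_est in sm_estimates:
        estimates = {sm_name: sm_est}
        flags = {}
        for db, table in db_lines.items():
            db_est = proportion_table(
                table, line_number, regimens=[sm_est.regimen], source=db
            )[0]
            estimates[db] = db_est
            flags[db] = overlap(sm_est, db_est)
        rows.append(ComparisonRow(line_number, sm_est.regimen, estimates, flags))
    assert [r.regimen for r in rows] == row_regimens
    return rows


def concordance_report(rows: list[ComparisonRow]) -> dict:
    """Summarize overlap verdicts per line plus the full grid."""
    by_line: dict[int, list[ComparisonRow]] = {}
    for row in rows:
        by_line.setdefault(row.line_number, []).append(row)
    summary = {}
    for line_number, line_rows in sorted(by_line.items()):
        n = len(line_rows)
        k = sum(r.any_overlap for r in line_rows)
        summary[line_number] = {
            "n_regimens": n,
            "n_any_overlap": k,
            "fraction_any_overlap": round(k / n, 3) if n else None,
        }
    grid = [
        {
            "line_number": r.line_number,
            "regimen": r.regimen,
            "any_overlap": r.any_overlap,
            "overlap_flags": dict(r.overlap_flags),
            "estimates": {
                src: {
                    "proportion": e.proportion,
                    "ci_half_width": e.ci_half_width,
                    "numerator": e.numerator,
                    "denominator": e.denominator,
                }
                for src, e in r.estimates.items()
            },
        }
        for r in rows
    ]
    return {"per_line": summary, "rows": grid}
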