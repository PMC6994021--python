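"""Published reference estimates for advanced/metastatic melanoma treatment
patterns (first-line initiation 2011-2017).

These are the printed summary statistics of a published comparison of a
social-media patient cohort against four US EMR/claims databases (Flatiron,
McKesson, MarketScan, PharMetrics+): per-source first-line year distributions,
per-line patient counts, and per-regimen proportion estimates with 95% CI
half-widths, including the publication's own annotation of which database
intervals were flagged as overlapping the social-media interval.

They serve two purposes: as reference inputs for concordance re-computation,
and as the empirical anchor for the synthetic cohort generator's defaults.
"""

from __future__ import annotations

from .compare import ProportionEstimate

__all__ = [
    "SOURCES",
    "SM_SOURCE",
    "LINE_DENOMINATORS",
    "FIRST_LINE_YEAR_COUNTS",
    "PUBLISHED_ESTIMATES",
    "published_estimate",
    "published_rows",
]

SM_SOURCE = "social_media"
DATABASES = ("flatiron", "mckesson", "marketscan", "pharmetrics")
SOURCES = DATABASES + (SM_SOURCE,)

#: Patients with data at lines 1/2/3 per source.
LINE_DENOMINATORS: dict[str, tuple[int, int, int]] = {
    "flatiron": (2666, 930, 326),
    "mckesson": (560, 260, 66),
    "marketscan": (3268, 1108, 514),
    "pharmetrics": (739, 339, 154),
    SM_SOURCE: (817, 226, 73),
}

#: First-line initiation year distribution per source, 2011-2017.
FIRST_LINE_YEAR_COUNTS: dict[str, dict[int, int]] = {
    "flatiron": {2011: 104, 2012: 233, 2013: 366, 2014: 519,
                 2015: 508, 2016: 508, 2017: 428},
    "marketscan": {2011: 160, 2012: 384, 2013: 560, 2014: 720,
                   2015: 508, 2016: 508, 2017: 428},
    "mckesson": {2011: 10, 2012: 24, 2013: 35, 2014: 130,
                 2015: 127, 2016: 127, 2017: 107},
    "pharmetrics": {2011: 28, 2012: 44, 2013: 126, 2014: 180,
                    2015: 127, 2016: 127, 2017: 107},
    SM_SOURCE: {2011: 40, 2012: 96, 2013: 140, 2014: 180,
                2015: 127, 2016: 127, 2017: 107},
}

# (line, regimen, source, proportion %, ci half-width %, flagged_overlap)
# flagged_overlap is the publication's bold annotation on database cells
# (None for the social-media column itself).
PUBLISHED_ESTIMATES: tuple[tuple[int, str, str, float, float, bool | None], ...] = (
    # line 1
    (1, "ipilimumab", "flatiron", 24.8, 1.6, False),
    (1, "ipilimumab", "mckesson", 45.2, 4.1, True),
    (1, "ipilimumab", "marketscan", 16.7, 1.3, False),
    (1, "ipilimumab", "pharmetrics", 34.9, 3.4, False),
    (1, "ipilimumab", SM_SOURCE, 42.2, 3.4, None),
    (1, "pembrolizumab", "flatiron", 13.6, 1.3, True),
    (1, "pembrolizumab", "mckesson", 18.8, 3.2, False),
    (1, "pembrolizumab", "marketscan", 5.8, 0.8, False),
    (1, "pembrolizumab", "pharmetrics", 12.5, 2.4, True),
    (1, "pembrolizumab", SM_SOURCE, 11.3, 2.2, None),
    (1, "vemurafenib", "flatiron", 10.2, 1.2, True),
    (1, "vemurafenib", "mckesson", 1.3, 0.9, False),
    (1, "vemurafenib", "marketscan", 5.4, 0.8, False),
    (1, "vemurafenib", "pharmetrics", 5.1, 1.6, False),
    (1, "vemurafenib", SM_SOURCE, 13.3, 2.3, None),
    (1, "dabrafenib+trametinib", "flatiron", 9.7, 1.1, False),
    (1, "dabrafenib+trametinib", "mckesson", 2.1, 1.2, False),
    (1, "dabrafenib+trametinib", "marketscan", 4.3, 0.7, True),
    (1, "dabrafenib+trametinib", "pharmetrics", 6.2, 1.7, True),
    (1, "dabrafenib+trametinib", SM_SOURCE, 5.5, 1.6, None),
    (1, "ipilimumab+nivolumab", "flatiron", 9.4, 1.1, False),
    (1, "ipilimumab+nivolumab", "mckesson", 13.8, 2.9, False),
    (1, "ipilimumab+nivolumab", "marketscan", 3.5, 0.6, False),
    (1, "ipilimumab+nivolumab", "pharmetrics", 9.7, 2.1, True),
    (1, "ipilimumab+nivolumab", SM_SOURCE, 6.0, 1.6, None),
    (1, "nivolumab", "flatiron", 8.7, 1.1, False),
    (1, "nivolumab", "mckesson", 13.6, 2.8, False),
    (1, "nivolumab", "marketscan", 3.1, 0.6, True),
    (1, "nivolumab", "pharmetrics", 11.5, 2.3, False),
    (1, "nivolumab", SM_SOURCE, 4.4, 1.4, None),
    # line 2
    (2, "pembrolizumab", "flatiron", 18.6, 2.5, True),
    (2, "pembrolizumab", "mckesson", 35.8, 5.8, False),
    (2, "pembrolizumab", "marketscan", 8.1, 1.6, False),
    (2, "pembrolizumab", "pharmetrics", 23.9, 4.5, False),
    (2, "pembrolizumab", SM_SOURCE, 16.4, 4.8, None),
    (2, "dabrafenib+trametinib", "flatiron", 13.7, 2.2, False),
    (2, "dabrafenib+trametinib", "mckesson", 1.9, 1.7, False),
    (2, "dabrafenib+trametinib", "marketscan", 6.1, 1.4, True),
    (2, "dabrafenib+trametinib", "pharmetrics", 9.4, 3.1, True),
    (2, "dabrafenib+trametinib", SM_SOURCE, 6.6, 3.2, None),
    (2, "ipilimumab", "flatiron", 13.7, 2.2, False),
    (2, "ipilimumab", "mckesson", 6.9, 3.1, False),
    (2, "ipilimumab", "marketscan", 9.1, 1.7, False),
    (2, "ipilimumab", "pharmetrics", 15.0, 3.8, True),
    (2, "ipilimumab", SM_SOURCE, 24.3, 5.6, None),
    (2, "nivolumab", "flatiron", 11.2, 2.0, True),
    (2, "nivolumab", "mckesson", 34.6, 5.8, False),
    (2, "nivolumab", "marketscan", 4.8, 1.3, False),
    (2, "nivolumab", "pharmetrics", 12.7, 3.5, True),
    (2, "nivolumab", SM_SOURCE, 11.5, 4.2, None),
    (2, "ipilimumab+nivolumab", "flatiron", 5.8, 1.5, False),
    (2, "ipilimumab+nivolumab", "mckesson", 10.0, 3.6, True),
    (2, "ipilimumab+nivolumab", "marketscan", 3.2, 1.0, False),
    (2, "ipilimumab+nivolumab", "pharmetrics", 3.8, 2.0, False),
    (2, "ipilimumab+nivolumab", SM_SOURCE, 8.4, 3.6, None),
    (2, "temozolomide", "flatiron", 5.3, 1.4, True),
    (2, "temozolomide", "mckesson", 0.8, 1.1, False),
    (2, "temozolomide", "marketscan", 4.6, 1.2, True),
    (2, "temozolomide", "pharmetrics", 4.4, 2.2, True),
    (2, "temozolomide", SM_SOURCE, 3.5, 2.4, None),
    # line 3
    (3, "pembrolizumab", "flatiron", 15.3, 3.9, False),
    (3, "pembrolizumab", "mckesson", 22.7, 10.1, False),
    (3, "pembrolizumab", "marketscan", 4.1, 1.7, True),
    (3, "pembrolizumab", "pharmetrics", 18.2, 6.1, False),
    (3, "pembrolizumab", SM_SOURCE, 4.1, 4.6, None),
    (3, "dabrafenib+trametinib", "flatiron", 12.9, 3.6, True),
    (3, "dabrafenib+trametinib", "mckesson", 0.0, 0.0, False),
    (3, "dabrafenib+trametinib", "marketscan", 7.0, 2.2, True),
    (3, "dabrafenib+trametinib", "pharmetrics", 13.0, 5.3, True),
    (3, "dabrafenib+trametinib", SM_SOURCE, 9.6, 6.8, None),
    (3, "nivolumab", "flatiron", 12.0, 3.5, True),
    (3, "nivolumab", "mckesson", 22.7, 10.1, True),
    (3, "nivolumab", "marketscan", 5.3, 1.9, False),
    (3, "nivolumab", "pharmetrics", 16.9, 5.9, True),
    (3, "nivolumab", SM_SOURCE, 19.2, 9.0, None),
    (3, "ipilimumab", "flatiron", 9.2, 3.1, True),
    (3, "ipilimumab", "mckesson", 9.1, 6.9, True),
    (3, "ipilimumab", "marketscan", 7.0, 2.2, False),
    (3, "ipilimumab", "pharmetrics", 10.4, 4.8, True),
    (3, "ipilimumab", SM_SOURCE, 16.4, 8.5, None),
    (3, "ipilimumab+nivolumab", "flatiron", 8.9, 3.1, True),
    (3, "ipilimumab+nivolumab", "mckesson", 18.2, 9.3, True),
    (3, "ipilimumab+nivolumab", "marketscan", 2.5, 1.4, False),
    (3, "ipilimumab+nivolumab", "pharmetrics", 2.6, 2.5, False),
    (3, "ipilimumab+nivolumab", SM_SOURCE, 12.3, 7.5, None),
    (3, "temozolomide", "flatiron", 4.9, 2.3, True),
    (3, "temozolomide", "mckesson", 0.0, 0.0, False),
    (3, "temozolomide", "marketscan", 3.3, 1.5, True),
    (3, "temozolomide", "pharmetrics", 5.2, 3.5, False),
    (3, "temozolomide", SM_SOURCE, 1.4, 2.7, None),
)


def published_estimate(line: int, regimen: str, source: str) -> ProportionEstimate:
    """One published cell as a ProportionEstimate (numerator reconstructed as
    round(p * n / 100) from the rounded printed proportion)."""
    for ln, reg, src, prop, hw, _ in PUBLISHED_ESTIMATES:
        if (ln, reg, src) == (line, regimen, source):
            n = LINE_DENOMINATORS[source][line - 1]
            return ProportionEstimate(
                source=source, line_number=line, regimen=reg,
                numerator=int(round(prop * n / 100.0)), denominator=n,
                proportion=prop, ci_half_width=hw,
            )
    raise KeyError((line, regimen, source))


def published_rows() -> list[tuple[int, str]]:
    """The 18 (line, regimen) rows of the published comparison."""
    seen = []
    for ln, reg, _, _, _, _ in PUBLISHED_ESTIMATES:
        if (ln, reg) not in seen:
            seen.append((ln, reg))
    return seen
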