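"""Negation filtering and temporal resolution for treatment mentions.

Negation follows a NegEx-style window rule: a cue ("not", "never", "refused",
...) within the five tokens preceding the mention negates it, unless a scope
terminator ("but", "however", ...) intervenes. Temporal resolution is total:
every sentence yields a date and a rule tag — an explicit expression
("in March 2014", "3/2014"), a relative offset ("three months ago",
"last year"), or the post date as default. Month-precision results use day 15.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date, timedelta
from importlib import resources

import pandas as pd
from dateutil.relativedelta import relativedelta

from .lexicon import TreatmentMention

__all__ = [
    "ResolvedMention",
    "detect_negation",
    "resolve_time",
    "resolve_mentions",
    "load_cue_list",
    "FUTURE_SLACK_DAYS",
]

#: Mentions dated more than this many days after the post are treated as
#: intent ("I will start pembro next month"), not receipt, and dropped.
FUTURE_SLACK_DAYS = 30

_TOKEN_RE = re.compile(r"[A-Za-z0-9][A-Za-z0-9'\-]*")
_NEGATION_WINDOW = 5  # tokens preceding the mention


def load_cue_list(name: str) -> tuple[str, ...]:
    """Load a bundled cue list (one cue per line, ``#`` comments)."""
    text = resources.files("forumrx.data").joinpath(name).read_text("utf-8")
    return tuple(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


_CUES = load_cue_list("negation_cues.txt")
_CUE_SINGLE = frozenset(c for c in _CUES if " " not in c)
_CUE_MULTI = tuple(tuple(c.split()) for c in _CUES if " " in c)
_TERMINATORS = frozenset(load_cue_list("negation_terminators.txt"))


@dataclass(frozen=True)
class ResolvedMention:
    """A treatment mention with its negation verdict and calendar anchor."""

    mention: TreatmentMention
    negated: bool
    event_date: date
    resolution_rule: str  # explicit_date | relative_offset | post_date_default


def detect_negation(sentence: str, mention_start: int) -> bool:
    """Is the mention starting at ``mention_start`` negated in ``sentence``?"""
    tokens = [(m.group().lower(), m.start()) for m in _TOKEN_RE.finditer(sentence)]
    idx = 0
    for i, (_, start) in enumerate(tokens):
        if start >= mention_start:
            idx = i
            break
    else:
        return False
    window_lo = max(0, idx - _NEGATION_WINDOW)
    window = [t for t, _ in tokens[window_lo:idx]]
    cue_pos = None
    for j, tok in enumerate(window):
        if tok in _CUE_SINGLE:
            cue_pos = j
        for multi in _CUE_MULTI:
            if tuple(window[j : j + len(multi)]) == multi:
                cue_pos = j + len(multi) - 1
    if cue_pos is None:
        return False
    return not any(t in _TERMINATORS for t in window[cue_pos + 1 :])


_MONTHS = {
    name: i + 1
    for i, name in enumerate(
        ["january", "february", "march", "april", "may", "june", "july",
         "august", "september", "october", "november", "december"]
    )
}
_MONTH_ALT = "|".join(m[:3] + r"(?:" + m[3:] + r")?" if len(m) > 3 else m
                      for m in _MONTHS)
_EXPLICIT_MONTH_RE = re.compile(
    rf"\b({_MONTH_ALT})\.?,?\s+((?:19|20)\d{{2}})\b", re.IGNORECASE
)
_EXPLICIT_NUM_RE = re.compile(r"\b(0?[1-9]|1[0-2])\s*/\s*((?:19|20)\d{2})\b")

_NUMBER_WORDS = {
    "a": 1, "an": 1, "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
    "six": 6, "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11,
    "twelve": 12,
}
_RELATIVE_RE = re.compile(
    r"\b(\d{1,3}|" + "|".join(_NUMBER_WORDS) + r")\s+"
    r"(day|week|month|year)s?\s+(?:ago|back)\b",
    re.IGNORECASE,
)
_LAST_RE = re.compile(r"\blast\s+(week|month|year)\b", re.IGNORECASE)


def _month_key(token: str) -> int:
    low = token.lower()
    for name, num in _MONTHS.items():
        if name.startswith(low[:3]) and (low == name[:3] or low == name):
            return num
    raise ValueError(token)


def resolve_time(sentence: str, post_date: date) -> tuple[date, str]:
    """Resolve the sentence's temporal expression relative to ``post_date``.

    Total: always returns ``(event_date, rule)``. Explicit month/year
    expressions anchor to day 15 of that month; relative offsets are
    subtracted from the post date; otherwise the post date itself is used.
    """
    m = _EXPLICIT_MONTH_RE.search(sentence)
    if m:
        return date(int(m.group(2)), _month_key(m.group(1)), 15), "explicit_date"
    m = _EXPLICIT_NUM_RE.search(sentence)
    if m:
        return date(int(m.group(2)), int(m.group(1)), 15), "explicit_date"
    m = _RELATIVE_RE.search(sentence)
    if m:
        raw = m.group(1).lower()
        n = _NUMBER_WORDS.get(raw) or int(raw)
        unit = m.group(2).lower()
        if unit == "day":
            event = post_date - timedelta(days=n)
        elif unit == "week":
            event = post_date - timedelta(weeks=n)
        elif unit == "month":
            event = post_date - relativedelta(months=n)
        else:
            event = post_date - relativedelta(years=n)
        return event, "relative_offset"
    m = _LAST_RE.search(sentence)
    if m:
        unit = m.group(1).lower()
        delta = {"week": timedelta(weeks=1), "month": relativedelta(months=1),
                 "year": relativedelta(years=1)}[unit]
        return post_date - delta, "relative_offset"
    return post_date, "post_date_default"


def resolve_mention(mention: TreatmentMention, sentence: str) -> ResolvedMention:
    """Attach negation verdict and event date to a single mention."""
    negated = detect_negation(sentence, mention.start)
    event_date, rule = resolve_time(sentence, mention.post_date)
    return ResolvedMention(mention, negated, event_date, rule)


def resolve_mentions(
    mentions: list[TreatmentMention],
    sentences: pd.DataFrame,
    verdicts: dict[tuple[str, str, int], str],
) -> list[ResolvedMention]:
    """Gate mentions through the receipt classifier and the negation filter,
    then attach event dates.

    ``verdicts`` maps (user_id, post_id, sentence_index) to "receipt" or
    "non_receipt". A mention survives iff its sentence was classified receipt,
    it is not negated, and its event date is not in the future (beyond
    ``FUTURE_SLACK_DAYS`` after the post). Raises KeyError when a mention's
    sentence lacks a classifier verdict.
    """
    text_by_key = {
        (r.user_id, r.post_id, r.sentence_index): r.text
        for r in sentences.itertuples()
    }
    kept: list[ResolvedMention] = []
    for mention in mentions:
        key = (mention.user_id, mention.post_id, mention.sentence_index)
        if key not in verdicts:
            raise KeyError(f"no classifier verdict for sentence {key}")
        if verdicts[key] != "receipt":
            continue
        resolved = resolve_mention(mention, text_by_key[key])
        if resolved.negated:
            continue
        if (resolved.event_date - mention.post_date).days > FUTURE_SLACK_DAYS:
            continue
        kept.append(resolved)
    return kept


def resolved_to_frame(resolved: list[ResolvedMention]) -> pd.DataFrame:
    """Tabular view used by the line-derivation stage and CSV export."""
    return pd.DataFrame(
        [
            {
                "user_id": r.mention.user_id,
                "forum": r.mention.forum,
                "post_date": r.mention.post_date,
                "post_id": r.mention.post_id,
                "sentence_index": r.mention.sentence_index,
                "canonical": r.mention.canonical,
                "surface": r.mention.surface,
                "negated": r.negated,
                "event_date": r.event_date,
                "resolution_rule": r.resolution_rule,
            }
            for r in resolved
        ],
        columns=["user_id", "forum", "post_date", "post_id", "sentence_index",
                 "canonical", "surface", "negated", "event_date",
                 "resolution_rule"],
    )
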