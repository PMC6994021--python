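"""Treatment vocabulary for advanced melanoma and mention detection.

Each lexicon entry maps a canonical generic drug name to its surface variants
(brand names, abbreviations, common misspellings). Matching is case-insensitive
whole-token matching over unigrams and two-token phrases, with bounded fuzzy
matching (Levenshtein distance <= 1, only for tokens of length >= 6) to absorb
typos like "temozolamide". Interferon and docetaxel carry an adjuvant flag:
downstream line derivation never counts them as a line when given alone.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from datetime import date
from importlib import resources

__all__ = [
    "LexiconError",
    "LexiconEntry",
    "TreatmentMention",
    "TreatmentLexicon",
    "load_lexicon",
    "default_lexicon",
    "find_mentions",
    "within_one_edit",
]

FUZZY_MIN_LEN = 6  # fuzzy matching never fires below this token length


class LexiconError(ValueError):
    """Malformed or ambiguous lexicon file."""


@dataclass(frozen=True)
class LexiconEntry:
    canonical: str
    variants: tuple[str, ...]
    adjuvant: bool = False


@dataclass(frozen=True)
class TreatmentMention:
    """A normalized drug detection in one sentence."""

    user_id: str
    forum: str
    post_date: date
    post_id: str
    sentence_index: int
    canonical: str
    surface: str
    start: int
    end: int


_TOKEN_RE = re.compile(r"[A-Za-z0-9][A-Za-z0-9'\-]*")


def within_one_edit(a: str, b: str) -> bool:
    """True iff Levenshtein distance between a and b is <= 1."""
    if a == b:
        return True
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la == lb:  # exactly one substitution allowed
        return sum(x != y for x, y in zip(a, b)) <= 1
    if la > lb:
        a, b, la, lb = b, a, lb, la
    # b is one longer: one deletion from b must give a
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1 :]


class TreatmentLexicon:
    """Validated variant->canonical mapping plus the adjuvant drug set."""

    def __init__(self, entries: list[LexiconEntry]):
        if not entries:
            raise LexiconError("lexicon has no entries")
        seen_canonical: set[str] = set()
        surface_map: dict[str, str] = {}
        for entry in entries:
            canon = entry.canonical.lower().strip()
            if canon in seen_canonical:
                raise LexiconError(f"duplicate canonical name: {entry.canonical!r}")
            seen_canonical.add(canon)
            if not entry.variants:
                raise LexiconError(f"{entry.canonical!r} has no variants")
            for surface in (canon, *entry.variants):
                key = surface.lower().strip()
                if not key:
                    raise LexiconError(f"empty variant under {entry.canonical!r}")
                if surface_map.get(key, canon) != canon:
                    raise LexiconError(
                        f"ambiguous variant {surface!r}: maps to both "
                        f"{surface_map[key]!r} and {canon!r}"
                    )
                surface_map[key] = canon
        self.entries = tuple(entries)
        self._surface_map = surface_map
        self._multi = {
            tuple(k.split()): v for k, v in surface_map.items() if " " in k
        }
        self._fuzzy_surfaces = sorted(
            (s, c) for s, c in surface_map.items()
            if len(s) >= FUZZY_MIN_LEN and " " not in s
        )
        self.adjuvant_drugs = frozenset(
            e.canonical.lower() for e in entries if e.adjuvant
        )

    @property
    def canonicals(self) -> frozenset[str]:
        return frozenset(e.canonical.lower() for e in self.entries)

    def variants_of(self, canonical: str) -> tuple[str, ...]:
        for e in self.entries:
            if e.canonical.lower() == canonical.lower():
                return e.variants
        raise KeyError(canonical)

    def normalize(self, surface: str) -> str | None:
        """Exact (case-insensitive) surface lookup; None if unknown."""
        return self._surface_map.get(surface.lower().strip())

    def scan(self, text: str, fuzzy: bool = True) -> list[tuple[str, str, int, int]]:
        """Find all mentions in ``text``.

        Returns ``(canonical, surface, start, end)`` tuples, leftmost-longest:
        a two-token phrase match beats a one-token match at the same position,
        and matched tokens are consumed. Tokens joined by ``/`` are examined
        separately, so ``"ipi/nivo"`` yields two mentions.
        """
        tokens = [(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]
        out: list[tuple[str, str, int, int]] = []
        i = 0
        while i < len(tokens):
            tok, start, end = tokens[i]
            low = tok.lower()
            # two-token phrase ("talimogene laherparepvec", "interleukin 2", ...)
            if i + 1 < len(tokens):
                nxt, _, nxt_end = tokens[i + 1]
                canon = self._multi.get((low, nxt.lower()))
                if canon is not None:
                    out.append((canon, f"{tok} {nxt}", start, nxt_end))
                    i += 2
                    continue
            canon = self._surface_map.get(low)
            if canon is not None:
                out.append((canon, tok, start, end))
                i += 1
                continue
            if fuzzy and len(low) >= FUZZY_MIN_LEN:
                hit = self._fuzzy_lookup(low)
                if hit is not None:
                    out.append((hit, tok, start, end))
            i += 1
        return out

    def _fuzzy_lookup(self, token: str) -> str | None:
        candidates = {
            canon for surface, canon in self._fuzzy_surfaces
            if within_one_edit(token, surface)
        }
        if candidates:
            return min(candidates)  # deterministic tie-break, alphabetical
        return None


def _entries_from_rows(rows) -> list[LexiconEntry]:
    by_canonical: dict[str, dict] = {}
    for row in rows:
        canon = row["canonical"].strip().lower()
        variant = row["variant"].strip()
        flag = str(row.get("adjuvant_flag", "")).strip().lower() in {
            "1", "true", "yes",
        }
        slot = by_canonical.setdefault(canon, {"variants": [], "adjuvant": False})
        if variant:
            slot["variants"].append(variant)
        slot["adjuvant"] = slot["adjuvant"] or flag
    return [
        LexiconEntry(canonical=c, variants=tuple(v["variants"]), adjuvant=v["adjuvant"])
        for c, v in by_canonical.items()
    ]


def load_lexicon(path) -> TreatmentLexicon:
    """Load a lexicon CSV with columns canonical, variant, adjuvant_flag."""
    with open(path, encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise LexiconError(f"empty lexicon file: {path}")
    return TreatmentLexicon(_entries_from_rows(rows))


def default_lexicon() -> TreatmentLexicon:
    """The bundled melanoma systemic-therapy lexicon (guideline-era drugs)."""
    data = resources.files("forumrx.data").joinpath("melanoma_lexicon.csv")
    with resources.as_file(data) as path:
        return load_lexicon(path)


def find_mentions(record, lexicon: TreatmentLexicon, fuzzy: bool = True
                  ) -> list[TreatmentMention]:
    """Detect and normalize treatment mentions in one sentence record."""
    return [
        TreatmentMention(
            user_id=record.user_id,
            forum=record.forum,
            post_date=record.post_date,
            post_id=record.post_id,
            sentence_index=record.sentence_index,
            canonical=canonical,
            surface=surface,
            start=start,
            end=end,
        )
        for canonical, surface, start, end in lexicon.scan(record.text, fuzzy=fuzzy)
    ]
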