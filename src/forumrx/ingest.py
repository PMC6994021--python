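"""Corpus ingestion: read forum post dumps, clean and sentence-tokenize text,
derive stable user ids, and filter to users with at least one treatment mention.

The unit handed to every downstream stage is the *sentence*: a row of the
analytic table ``(user_id, forum, post_date, post_id, sentence_index, text)``,
sorted chronologically within each user.
"""

from __future__ import annotations

import hashlib
import json
import re
import string
from dataclasses import dataclass
from datetime import date

import pandas as pd
from dateutil import parser as dateparser

__all__ = [
    "ForumPost",
    "SentenceRecord",
    "clean_text",
    "split_sentences",
    "make_user_id",
    "make_post_id",
    "read_posts_jsonl",
    "write_posts_jsonl",
    "build_sentence_table",
    "filter_treatment_users",
]


@dataclass(frozen=True)
class ForumPost:
    """A raw post as scraped/dumped: author handle, forum, post date, free text."""

    username: str
    forum: str
    post_date: date
    text: str


@dataclass(frozen=True)
class SentenceRecord:
    """One cleaned sentence of one post, keyed to a derived patient (user) id."""

    user_id: str
    forum: str
    post_date: date
    post_id: str
    sentence_index: int
    text: str


_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)

# Character whitelist: letters, digits, space and basic punctuation . , ! ? ' - /
_KEEP = frozenset(string.ascii_letters + string.digits + " .,!?'-/")

# Tokens before a "." that do not end a sentence.
_ABBREVIATIONS = frozenset(
    {"dr", "mr", "mrs", "ms", "prof", "st", "vs", "e.g", "i.e", "eg", "ie",
     "etc", "approx"}
)

_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s)")


def clean_text(raw: str) -> str:
    """Strip URLs and characters outside the whitelist; collapse whitespace.

    Non-whitelisted characters are replaced by a space rather than deleted so
    that separators like ``+`` or ``&`` keep adjacent tokens apart
    (``"ipi+nivo"`` -> ``"ipi nivo"``). Idempotent.
    """
    text = _URL_RE.sub(" ", raw)
    text = "".join(ch if ch in _KEEP else " " for ch in text)
    return " ".join(text.split())


def split_sentences(cleaned: str) -> list[str]:
    """Split cleaned text at ``.``, ``!`` or ``?`` followed by whitespace.

    A short abbreviation guard ("Dr.", "e.g.", ...) suppresses false breaks.
    The concatenation of the output equals the input up to boundary whitespace.
    """
    if not cleaned.strip():
        return []
    breaks: list[int] = []
    for m in _BOUNDARY_RE.finditer(cleaned):
        prefix = cleaned[: m.start()]
        last_word = prefix.rsplit(None, 1)[-1] if prefix.split() else ""
        if "." in m.group() and last_word.lower().rstrip(".") in _ABBREVIATIONS:
            continue
        breaks.append(m.end())
    sentences = []
    start = 0
    for b in breaks:
        piece = cleaned[start:b].strip()
        if piece:
            sentences.append(piece)
        start = b
    tail = cleaned[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def make_user_id(username: str, forum: str) -> str:
    """Derive the stable opaque patient id from (username, forum).

    The same handle on two different forums maps to two ids, reflecting the
    assumption that each (username, forum) pair is one unique patient.
    """
    if not username or not forum:
        raise ValueError("username and forum must both be non-empty")
    digest = hashlib.sha1(f"{username}\x1f{forum}".encode("utf-8")).hexdigest()
    return digest[:12]


def make_post_id(user_id: str, post_date: date, text: str) -> str:
    """Content-derived post key; identical (user, date, text) posts collide on
    purpose, which is what implements de-duplication."""
    digest = hashlib.sha1(
        f"{user_id}\x1f{post_date.isoformat()}\x1f{text}".encode("utf-8")
    ).hexdigest()
    return digest[:12]


def _parse_date(value) -> date:
    if isinstance(value, date):
        return value
    try:
        return dateparser.parse(str(value), dayfirst=False).date()
    except (ValueError, OverflowError) as exc:  # fail loudly, never drop silently
        raise ValueError(f"unparseable post date: {value!r}") from exc


def read_posts_jsonl(path) -> list[ForumPost]:
    """Read a JSONL dump with fields username, forum, post_date, text."""
    posts = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                posts.append(
                    ForumPost(
                        username=rec["username"],
                        forum=rec["forum"],
                        post_date=_parse_date(rec["post_date"]),
                        text=rec["text"],
                    )
                )
            except (KeyError, ValueError, json.JSONDecodeError) as exc:
                raise ValueError(f"{path}:{lineno}: bad post record ({exc})") from exc
    return posts


def write_posts_jsonl(posts, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(
                json.dumps(
                    {
                        "username": p.username,
                        "forum": p.forum,
                        "post_date": p.post_date.isoformat(),
                        "text": p.text,
                    }
                )
                + "\n"
            )


def build_sentence_table(posts, deduplicate: bool = True) -> pd.DataFrame:
    """Posts -> analytic sentence table.

    Columns: user_id, forum, post_date, post_id, sentence_index, text.
    Rows are sorted by (user_id, post_date, post_id, sentence_index) so each
    user's history reads from the earliest post to the most recent. Posts with
    identical (user_id, post_date, text) are de-duplicated.
    """
    rows = []
    seen: set[str] = set()
    for post in posts:
        user_id = make_user_id(post.username, post.forum)
        post_id = make_post_id(user_id, post.post_date, post.text)
        if deduplicate:
            if post_id in seen:
                continue
            seen.add(post_id)
        cleaned = clean_text(post.text)
        for idx, sentence in enumerate(split_sentences(cleaned)):
            rows.append(
                (user_id, post.forum, post.post_date, post_id, idx, sentence)
            )
    df = pd.DataFrame(
        rows,
        columns=["user_id", "forum", "post_date", "post_id", "sentence_index", "text"],
    )
    return df.sort_values(
        ["user_id", "post_date", "post_id", "sentence_index"], kind="stable"
    ).reset_index(drop=True)


def filter_treatment_users(sentences: pd.DataFrame, lexicon) -> pd.DataFrame:
    """Keep every sentence of every user with >=1 treatment mention anywhere.

    The filter is user-level: a single mention retains the user's whole
    history; users without any mention are dropped entirely.
    """
    if sentences.empty:
        return sentences.copy()
    has_mention = sentences["text"].map(lambda t: bool(lexicon.scan(t)))
    keep_users = set(sentences.loc[has_mention, "user_id"])
    return sentences[sentences["user_id"].isin(keep_users)].reset_index(drop=True)
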