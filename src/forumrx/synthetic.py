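"""Synthetic patient journeys, forum posts, and comparator cohort tables.

The generator emulates the statistical structure of a melanoma treatment-
pattern study: patients start 1-3 lines of systemic therapy between 2011 and
2017, with year-specific regimen mixes (drugs only appear after their US
approval era), and describe each line in short forum posts 0-90 days after
the event. Posts carry noise at configurable rates — injected one-edit typos,
brand names, negated mentions of drugs never received, off-topic chatter,
and relative rather than absolute date phrasing. Because every post is
rendered from a known journey, the generator also emits a sentence-level
receipt/non-receipt label table, which replaces manual curation for training
the relevance classifier, and comparator EMR/claims-style cohort tables drawn
from the same regimen distributions.

All randomness flows from one master seed through per-stage streams, so every
artifact is reproducible byte-for-byte.
"""

from __future__ import annotations

import string
import zlib
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from dateutil.relativedelta import relativedelta

from .ingest import ForumPost, clean_text, make_post_id, make_user_id, split_sentences
from .lexicon import TreatmentLexicon, default_lexicon

__all__ = [
    "ConfigError",
    "NoiseConfig",
    "SimulationConfig",
    "TruthLine",
    "TruthJourney",
    "generate_truth",
    "render_posts",
    "render_comparators",
    "truth_lines_table",
    "write_truth_csv",
    "write_labels_csv",
    "write_comparators_csv",
    "stage_rng",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible RNG stream for one pipeline stage."""
    return np.random.default_rng([zlib.crc32(stage.encode("utf-8")), int(seed)])


# --------------------------------------------------------------------------
# configuration

#: First-line initiation years of the emulated social-media cohort
#: (2011-2017), as per-year patient counts.
DEFAULT_YEAR_COUNTS = {2011: 40, 2012: 96, 2013: 140, 2014: 180,
                       2015: 127, 2016: 127, 2017: 107}

#: Base per-line regimen mixes (before approval-year gating). Labels are
#: '+'-joined sorted canonical drug names.
DEFAULT_REGIMEN_WEIGHTS = {
    1: {
        "ipilimumab": 0.42, "vemurafenib": 0.13, "pembrolizumab": 0.11,
        "temozolomide": 0.07, "dabrafenib+trametinib": 0.06,
        "ipilimumab+nivolumab": 0.06, "nivolumab": 0.05, "dacarbazine": 0.05,
        "interleukin-2": 0.03, "carboplatin+paclitaxel": 0.02,
    },
    2: {
        "ipilimumab": 0.24, "pembrolizumab": 0.16, "nivolumab": 0.12,
        "carboplatin+paclitaxel": 0.10, "ipilimumab+nivolumab": 0.08,
        "vemurafenib": 0.08, "dabrafenib+trametinib": 0.07,
        "dacarbazine": 0.06, "interleukin-2": 0.05, "temozolomide": 0.04,
    },
    3: {
        "nivolumab": 0.19, "ipilimumab": 0.16, "ipilimumab+nivolumab": 0.12,
        "carboplatin+paclitaxel": 0.12, "dabrafenib+trametinib": 0.10,
        "dacarbazine": 0.08, "interleukin-2": 0.08, "vemurafenib": 0.06,
        "temozolomide": 0.05, "pembrolizumab": 0.04,
    },
}

#: First year a regimen can be initiated (US approval era); absent = always.
DEFAULT_INTRO_YEARS = {
    "ipilimumab": 2011, "vemurafenib": 2011, "dabrafenib+trametinib": 2014,
    "pembrolizumab": 2014, "nivolumab": 2014, "ipilimumab+nivolumab": 2015,
}

#: Relative forum sizes of the emulated sources.
DEFAULT_FORUMS = ("melanoma.org", "melanoma-international",
                  "cancer-compass", "cancer-survival-network")
DEFAULT_FORUM_WEIGHTS = (23064, 5188, 414, 135)

#: Comparator pool sizes: patients per database per first-line year.
DEFAULT_COMPARATOR_POOLS = {
    "flatiron": {2011: 104, 2012: 233, 2013: 366, 2014: 519,
                 2015: 508, 2016: 508, 2017: 428},
    "marketscan": {2011: 160, 2012: 384, 2013: 560, 2014: 720,
                   2015: 508, 2016: 508, 2017: 428},
    "mckesson": {2011: 10, 2012: 24, 2013: 35, 2014: 130,
                 2015: 127, 2016: 127, 2017: 107},
    "pharmetrics": {2011: 28, 2012: 44, 2013: 126, 2014: 180,
                    2015: 127, 2016: 127, 2017: 107},
}


@dataclass(frozen=True)
class NoiseConfig:
    """Rates of the corpus-level noise processes, each in [0, 1]."""

    typo_rate: float = 0.1          # one-edit typo on a drug surface form
    negation_rate: float = 0.1      # per-patient negated mention of a decoy drug
    offtopic_rate: float = 0.1      # per-patient off-topic chatter posts
    discussion_rate: float = 0.1    # per-patient non-receipt drug discussion
    relative_date_rate: float = 0.3  # relative ("three months ago") phrasing

    @classmethod
    def uniform(cls, level: float) -> "NoiseConfig":
        return cls(level, level, level, level, level)

    @classmethod
    def zero(cls) -> "NoiseConfig":
        return cls.uniform(0.0)

    def validate(self) -> None:
        for name in ("typo_rate", "negation_rate", "offtopic_rate",
                     "discussion_rate", "relative_date_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} out of [0, 1]: {v}")


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth generator settings.

    Defaults reproduce the emulated study's marginals: the 2011-2017 first-line
    year distribution, P(second line) = 226/817, P(third | second) = 73/226,
    and per-line regimen mixes anchored to the observed social-media columns
    with a remainder bucket over older agents.
    """

    n_patients: int = 1000
    year_counts: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_YEAR_COUNTS))
    regimen_weights: dict[int, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_REGIMEN_WEIGHTS.items()})
    regimen_intro_years: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_INTRO_YEARS))
    p_second_line: float = 226 / 817
    p_third_line: float = 73 / 226
    adjuvant_decoy_rate: float = 0.1
    brand_rate: float = 0.3
    line_gap_months: tuple[int, int] = (3, 15)  # inclusive bounds
    post_lag_days: tuple[int, int] = (0, 90)    # inclusive bounds
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    comparator_pools: dict[str, dict[int, int]] = field(
        default_factory=lambda: {db: dict(y) for db, y in DEFAULT_COMPARATOR_POOLS.items()})
    forums: tuple[str, ...] = DEFAULT_FORUMS
    forum_weights: tuple[float, ...] = DEFAULT_FORUM_WEIGHTS
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        for p_name in ("p_second_line", "p_third_line", "adjuvant_decoy_rate",
                       "brand_rate"):
            v = getattr(self, p_name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{p_name} out of [0, 1]: {v}")
        self.noise.validate()
        if not self.year_counts or any(c < 0 for c in self.year_counts.values()):
            raise ConfigError("year_counts must be non-empty and non-negative")
        if not self.regimen_weights:
            raise ConfigError("regimen_weights must not be empty")
        for line, weights in self.regimen_weights.items():
            if not weights:
                raise ConfigError(f"empty regimen distribution for line {line}")
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"line {line} regimen weights sum to {total}, not 1")
            if any(w < 0 for w in weights.values()):
                raise ConfigError(f"negative regimen weight at line {line}")
        for db, pool in self.comparator_pools.items():
            if any(c < 0 for c in pool.values()):
                raise ConfigError(f"negative pool count for {db}")

    def effective_regimen_weights(self, year: int, line: int) -> dict[str, float]:
        """Regimen mix available in ``year`` at ``line`` (gated, renormalized)."""
        base = self.regimen_weights[min(line, max(self.regimen_weights))]
        avail = {r: w for r, w in base.items()
                 if self.regimen_intro_years.get(r, 0) <= year and w > 0}
        if not avail:
            raise ConfigError(f"no regimen available in {year} at line {line}")
        total = sum(avail.values())
        return {r: w / total for r, w in avail.items()}


# --------------------------------------------------------------------------
# ground truth

@dataclass(frozen=True)
class TruthLine:
    line_number: int
    regimen: frozenset[str]
    start_date: date


@dataclass(frozen=True)
class TruthJourney:
    """One simulated patient: identity plus ordered therapy lines. Adjuvant
    exposures (interferon/docetaxel monotherapy before first line) are decoys
    rendered in posts but never counted as truth lines."""

    patient_id: str
    forum: str
    username: str
    lines: tuple[TruthLine, ...]
    adjuvant_exposures: tuple[tuple[str, date], ...] = ()

    @property
    def drugs(self) -> frozenset[str]:
        out: set[str] = set()
        for line in self.lines:
            out |= line.regimen
        return frozenset(out)


def _regimen_set(label: str) -> frozenset[str]:
    return frozenset(label.split("+"))


def _sample_lines(rng: np.random.Generator, config: SimulationConfig,
                  first_year: int) -> list[TruthLine]:
    month = int(rng.integers(1, 13))
    start = date(first_year, month, 15)
    n_lines = 1
    if rng.random() < config.p_second_line:
        n_lines += 1
        if rng.random() < config.p_third_line:
            n_lines += 1
    lines: list[TruthLine] = []
    prev: frozenset[str] = frozenset()
    lo, hi = config.line_gap_months
    for k in range(1, n_lines + 1):
        if k > 1:
            start = start + relativedelta(months=int(rng.integers(lo, hi + 1)))
        weights = config.effective_regimen_weights(start.year, k)
        labels = sorted(weights)
        probs = np.array([weights[l] for l in labels])
        for _ in range(100):
            regimen = _regimen_set(str(rng.choice(labels, p=probs)))
            if regimen - prev:  # a later line must introduce a new drug
                break
        else:  # pragma: no cover - only with a single-regimen distribution
            break
        lines.append(TruthLine(k, regimen, start))
        prev = regimen
    return lines


def generate_truth(config: SimulationConfig) -> list[TruthJourney]:
    """Draw ``config.n_patients`` ground-truth journeys."""
    rng = stage_rng(config.seed, "truth")
    years = sorted(config.year_counts)
    year_probs = np.array([config.year_counts[y] for y in years], dtype=float)
    year_probs /= year_probs.sum()
    forum_probs = np.array(config.forum_weights, dtype=float)
    forum_probs /= forum_probs.sum()
    journeys = []
    for i in range(config.n_patients):
        username = f"user_{i:05d}"
        forum = str(rng.choice(config.forums, p=forum_probs))
        first_year = int(rng.choice(years, p=year_probs))
        lines = _sample_lines(rng, config, first_year)
        decoys: tuple[tuple[str, date], ...] = ()
        if rng.random() < config.adjuvant_decoy_rate:
            drug = str(rng.choice(["interferon", "docetaxel"]))
            lead = int(rng.integers(6, 25))
            decoys = ((drug, lines[0].start_date - relativedelta(months=lead)),)
        journeys.append(
            TruthJourney(
                patient_id=make_user_id(username, forum),
                forum=forum,
                username=username,
                lines=tuple(lines),
                adjuvant_exposures=decoys,
            )
        )
    return journeys


# --------------------------------------------------------------------------
# post rendering

RECEIPT_TEMPLATES = (
    "I started {drugs} {when}.",
    "Started {drugs} {when} and so far so good.",
    "My onc put me on {drugs} {when}.",
    "I received {drugs} {when}.",
    "Began {drugs} {when} after my last scan.",
    "My first infusion of {drugs} was {when}.",
    "They switched me to {drugs} {when}.",
    # receipt phrased with "considering"-style vocabulary, as real posters do
    "They offered me {drugs} {when} and I said yes.",
    "My onc mentioned a trial first and we went with {drugs} {when}.",
    "I asked about every option and ended up on {drugs} {when}.",
    "After weighing the options I decided on {drugs} {when}.",
)

DISCUSSION_TEMPLATES = (
    "My doctor mentioned {drugs} as an option.",
    "Has anyone here tried {drugs}?",
    "Thinking about asking my onc about {drugs}.",
    "I read that {drugs} can cause bad fatigue.",
    "A friend from my support group was on {drugs}.",
    "They offered me {drugs} and I am still deciding.",
    "Is {drugs} worth the side effects?",
    "They want to start me on {drugs} soon.",
)

#: Building blocks for proxy/hedge non-receipt sentences: receipt vocabulary
#: ("started", dates) flipped by a single rare marker word, the pattern that
#: defeats token-counting classifiers in real forum text.
PROXY_RELATIONS = ("husband", "wife", "sister", "brother", "mom", "dad",
                   "aunt", "uncle", "neighbor", "friend", "coworker", "cousin")
HEDGE_OPENERS = ("I almost started", "I nearly started", "I very nearly began",
                 "I was supposed to start", "I was all set to start",
                 "I was scheduled to start", "I was planning to start",
                 "I was hoping to start", "I was leaning toward starting")
HEDGE_ENDINGS = ("and it fell through", "and then plans changed",
                 "and insurance got in the way", "and we held off")
PROXY_HEDGE_SHARE = 0.5  # share of discussion posts that are proxy/hedge

#: Oblique phrasings that real posters use both when reporting an actual start
#: and when merely discussing a plan; emitted by both classes, so the
#: classification task has an irreducible error floor like curated forum data.
AMBIGUOUS_TEMPLATES = (
    "Next step is {drugs} {when}.",
    "My onc brought up {drugs} {when}.",
    "We settled on {drugs} {when}.",
    "Moving to {drugs} {when}.",
)

#: Probability that a receipt / discussion sentence uses an oblique phrasing.
AMBIGUOUS_RECEIPT_SHARE = 0.05
AMBIGUOUS_DISCUSSION_SHARE = 0.2

NEGATED_TEMPLATES = (
    "I did not take {drugs}.",
    "I never started {drugs}.",
    "My onc said no to {drugs}.",
    "I decided not to do {drugs}.",
    "I refused {drugs} because of the side effects.",
    "We could not get {drugs} approved by insurance.",
    "I have not had {drugs}.",
)

OFFTOPIC_TEMPLATES = (
    "Sending good thoughts to everyone here.",
    "My scan results come back next week.",
    "Anyone have tips for dealing with fatigue?",
    "It was a beautiful day for a long walk.",
    "Thank you all for the kind words.",
    "My daughter graduated this weekend and I cried happy tears.",
    "Insurance paperwork is driving me crazy.",
    "Chemo was rough on my mom years ago.",
    "The infusion center staff are angels.",
    "Treatment decisions are so hard some days.",
    "Started physical therapy for my shoulder and it helps.",
)

#: Conversational filler attached to sentences of every class. Filler tokens
#: carry no label signal but dominate token counts, which is what makes real
#: forum text hard for neighbor- and count-based classifiers. None of these
#: contain negation cues, scope terminators, or temporal expressions.
PREFIX_POOL = (
    "Hi everyone", "Quick update from me", "Well", "So", "Hey all",
    "Long time lurker here and finally posting", "Checking in again",
    "After a lot of back and forth with the insurance people",
    "Per my onc at the big center two hours from us", "At my last visit",
    "After the scan came back and we met the whole team", "Honestly",
    "Good news I think", "Finally some movement on the plan front",
    "Deep breath", "For those following along at home",
    "Quick note before bed because tomorrow is an early one", "Update time",
    "Sorry I have been quiet lately with everything going on",
    "It has been a whirlwind of appointments and phone calls",
)
SUFFIX_POOL = (
    "fingers crossed", "praying it works this time around",
    "side effects so far are mild which is a huge relief",
    "feeling hopeful", "will keep you all posted as things develop",
    "thanks for the support here it means more than you know",
    "the fatigue is real", "one day at a time", "trying to stay positive",
    "my family is relieved beyond words", "still processing it all",
    "hoping for clear scans in the spring", "grateful for this group",
    "more soon", "wish me luck", "sending strength to everyone reading",
    "the waiting is the hardest part honestly",
)
FILLER_RATE = 0.55  # chance of a prefix and, independently, of a suffix
FILLER_STACK_RATE = 0.35  # chance a second filler is appended to the first

_MONTH_NAMES = ("January", "February", "March", "April", "May", "June", "July",
                "August", "September", "October", "November", "December")
_NUMBER_WORDS = ("zero", "one", "two", "three", "four", "five", "six", "seven",
                 "eight", "nine", "ten", "eleven", "twelve")


def _one_edit(word: str, rng: np.random.Generator) -> str:
    """One random edit (substitute/insert/delete a letter), keeping len >= 6."""
    letters = string.ascii_lowercase
    positions = [i for i, ch in enumerate(word) if ch.isalpha()]
    ops = ["sub", "ins"] + (["del"] if len(word) >= 7 else [])
    op = str(rng.choice(ops))
    i = int(rng.choice(positions))
    if op == "sub":
        repl = str(rng.choice([c for c in letters if c != word[i]]))
        return word[:i] + repl + word[i + 1:]
    if op == "ins":
        return word[:i] + str(rng.choice(list(letters))) + word[i:]
    return word[:i] + word[i + 1:]


def _drug_surface(drug: str, lexicon: TreatmentLexicon, config: SimulationConfig,
                  rng: np.random.Generator) -> str:
    surface = drug
    if rng.random() < config.brand_rate:
        variants = lexicon.variants_of(drug)
        if variants:
            surface = str(rng.choice(list(variants)))
    if (rng.random() < config.noise.typo_rate and len(surface) >= 6
            and " " not in surface):
        surface = _one_edit(surface, rng)
    return surface


def _drug_phrase(regimen, lexicon, config, rng) -> str:
    surfaces = [_drug_surface(d, lexicon, config, rng) for d in sorted(regimen)]
    if len(surfaces) == 1:
        return surfaces[0]
    joiner = str(rng.choice([" and ", "/"]))
    return joiner.join(surfaces)


def _month_diff(later: date, earlier: date) -> int:
    return (later.year - earlier.year) * 12 + (later.month - earlier.month)


def _when_phrase(event: date, post_date: date, config: SimulationConfig,
                 rng: np.random.Generator) -> str:
    if rng.random() < config.noise.relative_date_rate:
        n = _month_diff(post_date, event)
        if n == 0:
            return ""  # resolver falls back to the post date (same month)
        word = _NUMBER_WORDS[n] if (n <= 12 and rng.random() < 0.5) else str(n)
        unit = "month" if n == 1 else "months"
        return f"{word} {unit} ago"
    return f"in {_MONTH_NAMES[event.month - 1]} {event.year}"


def _corrupt_filler(phrase: str, rng: np.random.Generator,
                    word_typo_rate: float) -> str:
    """Spelling mistakes in conversational filler (never in template cores,
    drug names, dates, or negation cues, which are handled separately)."""
    words = phrase.split()
    out = []
    for w in words:
        if len(w) >= 4 and w.isalpha() and rng.random() < word_typo_rate:
            out.append(_one_edit(w.lower(), rng))
        else:
            out.append(w)
    return " ".join(out)


def _fill(template: str, drugs: str, when: str = "",
          rng: np.random.Generator | None = None,
          word_typo_rate: float = 0.0) -> str:
    text = template.format(drugs=drugs, when=when)
    text = " ".join(text.split())
    text = text.replace(" .", ".").replace(" ?", "?")
    if rng is not None:
        if rng.random() < FILLER_RATE:
            parts = [str(rng.choice(PREFIX_POOL))]
            if rng.random() < FILLER_STACK_RATE:
                parts.append(str(rng.choice(PREFIX_POOL)))
            prefix = _corrupt_filler(", ".join(parts), rng, word_typo_rate)
            text = f"{prefix}, {text[0].lower()}{text[1:]}"
        if rng.random() < FILLER_RATE:
            parts = [str(rng.choice(SUFFIX_POOL))]
            if rng.random() < FILLER_STACK_RATE:
                parts.append(str(rng.choice(SUFFIX_POOL)))
            suffix = _corrupt_filler(", ".join(parts), rng, word_typo_rate)
            text = f"{text[:-1]}, {suffix}{text[-1]}"
    return text


def _receipt_post(journey, event_date, regimen, lexicon, config, rng) -> ForumPost:
    lo, hi = config.post_lag_days
    post_date = event_date + timedelta(days=int(rng.integers(lo, hi + 1)))
    pool = (AMBIGUOUS_TEMPLATES
            if rng.random() < AMBIGUOUS_RECEIPT_SHARE else RECEIPT_TEMPLATES)
    text = _fill(str(rng.choice(pool)),
                 _drug_phrase(regimen, lexicon, config, rng),
                 _when_phrase(event_date, post_date, config, rng), rng=rng,
                 word_typo_rate=1.5 * config.noise.typo_rate)
    return ForumPost(journey.username, journey.forum, post_date, text)


def _discussion_post(journey, anchor, drug, lexicon, config, rng) -> ForumPost:
    post_date = anchor + timedelta(days=int(rng.integers(0, 181)))
    roll = rng.random()
    if roll < PROXY_HEDGE_SHARE:
        if rng.random() < 0.5:
            template = ("My " + str(rng.choice(PROXY_RELATIONS))
                        + " started {drugs} {when}.")
        else:
            template = (str(rng.choice(HEDGE_OPENERS)) + " {drugs} {when} "
                        + str(rng.choice(HEDGE_ENDINGS)) + ".")
    elif roll < PROXY_HEDGE_SHARE + AMBIGUOUS_DISCUSSION_SHARE:
        template = str(rng.choice(AMBIGUOUS_TEMPLATES))
    else:
        template = str(rng.choice(DISCUSSION_TEMPLATES))
    # a nearby (non-event) date keeps temporal tokens present in both classes
    pseudo_event = post_date - timedelta(days=int(rng.integers(0, 91)))
    text = _fill(template,
                 _drug_phrase({drug}, lexicon, config, rng),
                 _when_phrase(pseudo_event, post_date, config, rng), rng=rng,
                 word_typo_rate=1.5 * config.noise.typo_rate)
    return ForumPost(journey.username, journey.forum, post_date, text)


def _decoy_drug(journey: TruthJourney, config: SimulationConfig,
                rng: np.random.Generator) -> str | None:
    """A drug the patient never received, drawn from the era's regimen mix
    (posters discuss the treatments of their day, not arbitrary agents)."""
    year = journey.lines[0].start_date.year
    weights: dict[str, float] = {}
    for label, w in config.effective_regimen_weights(year, 1).items():
        drugs = label.split("+")
        for drug in drugs:
            weights[drug] = weights.get(drug, 0.0) + w / len(drugs)
    pool = {d: w for d, w in weights.items() if d not in journey.drugs}
    if not pool:
        return None
    names = sorted(pool)
    probs = np.array([pool[n] for n in names])
    return str(rng.choice(names, p=probs / probs.sum()))


def render_posts(
    journeys: list[TruthJourney],
    config: SimulationConfig,
    lexicon: TreatmentLexicon | None = None,
) -> tuple[list[ForumPost], pd.DataFrame]:
    """Render journeys as noisy forum posts plus a sentence-level label table.

    Every truth line yields at least one affirmative receipt post whose
    temporal expression resolves back to the line's start month. The label
    table marks each cleaned sentence receipt/non_receipt, keyed exactly as
    the ingest stage keys sentences (user_id, post_id, sentence_index).
    """
    if not journeys:
        raise ValueError("no journeys to render")
    lexicon = lexicon or default_lexicon()
    rng = stage_rng(config.seed, "posts")
    noise = config.noise
    canonicals = sorted(lexicon.canonicals)
    posts: list[tuple[ForumPost, str]] = []

    for journey in journeys:
        anchor = journey.lines[0].start_date
        for line in journey.lines:
            n_posts = 1 + int(rng.random() < 0.3)
            for _ in range(n_posts):
                posts.append(
                    (_receipt_post(journey, line.start_date, line.regimen,
                                   lexicon, config, rng), "receipt"))
        for drug, exposure_date in journey.adjuvant_exposures:
            posts.append(
                (_receipt_post(journey, exposure_date, {drug},
                               lexicon, config, rng), "receipt"))
        if rng.random() < noise.negation_rate:
            drug = _decoy_drug(journey, config, rng) or canonicals[0]
            post_date = anchor + timedelta(days=int(rng.integers(0, 181)))
            text = _fill(str(rng.choice(NEGATED_TEMPLATES)),
                         _drug_phrase({drug}, lexicon, config, rng), rng=rng,
                         word_typo_rate=1.5 * config.noise.typo_rate)
            posts.append(
                (ForumPost(journey.username, journey.forum, post_date, text),
                 "non_receipt"))
        if rng.random() < noise.discussion_rate:
            drug = _decoy_drug(journey, config, rng) or canonicals[0]
            posts.append(
                (_discussion_post(journey, anchor, drug, lexicon, config, rng),
                 "non_receipt"))
        if rng.random() < noise.offtopic_rate:
            for _ in range(1 + int(rng.random() < 0.5)):
                post_date = anchor + timedelta(days=int(rng.integers(0, 181)))
                text = _fill(str(rng.choice(OFFTOPIC_TEMPLATES)), "", rng=rng,
                             word_typo_rate=1.5 * config.noise.typo_rate)
                posts.append(
                    (ForumPost(journey.username, journey.forum, post_date, text),
                     "non_receipt"))

    label_rows = {}
    for post, label in posts:
        user_id = make_user_id(post.username, post.forum)
        post_id = make_post_id(user_id, post.post_date, post.text)
        for idx, _ in enumerate(split_sentences(clean_text(post.text))):
            label_rows[(user_id, post_id, idx)] = label
    labels = pd.DataFrame(
        [(u, p, i, lab) for (u, p, i), lab in sorted(label_rows.items())],
        columns=["user_id", "post_id", "sentence_index", "label"],
    )
    return [p for p, _ in posts], labels


# --------------------------------------------------------------------------
# comparator cohorts

def render_comparators(config: SimulationConfig) -> pd.DataFrame:
    """Draw comparator cohort line tables from the configured pools.

    Output schema matches the social-media line table (patient_id,
    line_number, regimen, start_date) plus database and first_line_year, so
    downstream matching and comparison are source-agnostic.
    """
    rng = stage_rng(config.seed, "comparators")
    rows = []
    for db in sorted(config.comparator_pools):
        pool = config.comparator_pools[db]
        for year in sorted(pool):
            for i in range(pool[year]):
                patient_id = f"{db}-{year}-{i:05d}"
                for line in _sample_lines(rng, config, year):
                    rows.append(
                        (patient_id, db, year, line.line_number,
                         "+".join(sorted(line.regimen)), line.start_date)
                    )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "database", "first_line_year", "line_number",
                 "regimen", "start_date"],
    )


# --------------------------------------------------------------------------
# tabular views and writers

def truth_lines_table(journeys: list[TruthJourney]) -> pd.DataFrame:
    """Ground-truth lines in the shared line-table schema."""
    rows = [
        (j.patient_id, line.line_number, "+".join(sorted(line.regimen)),
         line.start_date)
        for j in journeys
        for line in j.lines
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "line_number", "regimen", "start_date"]
    )


def write_truth_csv(journeys: list[TruthJourney], path) -> None:
    truth_lines_table(journeys).to_csv(path, index=False)


def write_labels_csv(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, index=False)


def write_comparators_csv(comparators: pd.DataFrame, path) -> None:
    comparators.to_csv(path, index=False)
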