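"""Negation windows and temporal resolution."""

from datetime import date

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forumrx.context import (FUTURE_SLACK_DAYS, detect_negation,
                             resolve_mentions, resolve_time)
from forumrx.lexicon import find_mentions


class TestNegation:
    def _negated(self, sentence, drug_surface):
        start = sentence.index(drug_surface)
        return detect_negation(sentence, start)

    def test_did_not_take(self):
        assert self._negated("I did not take temozolomide", "temozolomide")

    def test_plain_affirmative(self):
        assert not self._negated("I took ipilimumab", "ipilimumab")

    def test_terminator_between_cue_and_mention(self):
        s = "They said no to surgery but I started nivolumab"
        assert not self._negated(s, "nivolumab")

    def test_cue_outside_five_token_window(self):
        s = "never mind the delays the insurance the doctors I started ipilimumab"
        assert not self._negated(s, "ipilimumab")

    @pytest.mark.parametrize("cue", ["never", "refused", "declined", "didn't"])
    def test_cue_variants(self, cue):
        s = f"I {cue} ipilimumab"
        assert self._negated(s, "ipilimumab")


class TestResolveTime:
    def test_relative_months(self):
        event, rule = resolve_time("I received temozolomide three months ago",
                                   date(2015, 6, 20))
        assert (event, rule) == (date(2015, 3, 20), "relative_offset")

    def test_explicit_month_name(self):
        event, rule = resolve_time("started ipi in March 2014", date(2019, 1, 1))
        assert (event, rule) == (date(2014, 3, 15), "explicit_date")

    def test_explicit_numeric_month(self):
        event, rule = resolve_time("began treatment 3/2014", date(2019, 1, 1))
        assert (event, rule) == (date(2014, 3, 15), "explicit_date")

    def test_default_is_post_date(self):
        event, rule = resolve_time("I am on nivo", date(2016, 2, 1))
        assert (event, rule) == (date(2016, 2, 1), "post_date_default")

    def test_last_month(self):
        event, rule = resolve_time("started it last month", date(2016, 3, 10))
        assert (event, rule) == (date(2016, 2, 10), "relative_offset")

    def test_numeric_relative(self):
        event, rule = resolve_time("2 weeks ago it began", date(2016, 3, 15))
        assert (event, rule) == (date(2016, 3, 1), "relative_offset")

    @settings(max_examples=150, derandomize=True)
    @given(st.text(max_size=60),
           st.dates(min_value=date(2011, 1, 1), max_value=date(2020, 1, 1)))
    def test_total_on_arbitrary_text(self, text, post_date):
        event, rule = resolve_time(text, post_date)
        assert isinstance(event, date)
        assert rule in {"explicit_date", "relative_offset", "post_date_default"}


def _sentence_frame(record):
    return pd.DataFrame(
        [{
            "user_id": record.user_id, "forum": record.forum,
            "post_date": record.post_date, "post_id": record.post_id,
            "sentence_index": record.sentence_index, "text": record.text,
        }]
    )


class TestResolveMentions:
    def _run(self, text, verdict, lexicon, sentence_record, post_date=None):
        kwargs = {"post_date": post_date} if post_date else {}
        record = sentence_record(text, **kwargs)
        mentions = find_mentions(record, lexicon)
        verdicts = {(record.user_id, record.post_id, record.sentence_index): verdict}
        return resolve_mentions(mentions, _sentence_frame(record), verdicts)

    def test_receipt_and_negated_dropped(self, lexicon, sentence_record):
        kept = self._run("I did not take temozolomide", "receipt", lexicon,
                         sentence_record)
        assert kept == []

    def test_non_receipt_affirmative_dropped(self, lexicon, sentence_record):
        kept = self._run("I started ipilimumab", "non_receipt", lexicon,
                         sentence_record)
        assert kept == []

    def test_receipt_affirmative_kept_with_date(self, lexicon, sentence_record):
        kept = self._run("I started ipilimumab in March 2014", "receipt",
                         lexicon, sentence_record)
        assert len(kept) == 1
        assert kept[0].event_date == date(2014, 3, 15)
        assert not kept[0].negated

    def test_future_dated_mention_excluded(self, lexicon, sentence_record):
        kept = self._run("I start pembro in January 2020", "receipt", lexicon,
                         sentence_record, post_date=date(2019, 6, 1))
        assert kept == []  # 2020-01-15 is > FUTURE_SLACK_DAYS after the post
        assert FUTURE_SLACK_DAYS == 30

    def test_missing_verdict_is_an_error(self, lexicon, sentence_record):
        record = sentence_record("I started ipilimumab")
        mentions = find_mentions(record, lexicon)
        with pytest.raises(KeyError):
            resolve_mentions(mentions, _sentence_frame(record), verdicts={})
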