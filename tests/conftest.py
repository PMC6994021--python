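from datetime import date

import pytest

from forumrx.ingest import SentenceRecord
from forumrx.lexicon import default_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture
def sentence_record():
    def make(text, post_date=date(2015, 6, 20), user_id="u1", forum="f",
             post_id="p1", sentence_index=0):
        return SentenceRecord(user_id=user_id, forum=forum,
                              post_date=post_date, post_id=post_id,
                              sentence_index=sentence_index, text=text)

    return make
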