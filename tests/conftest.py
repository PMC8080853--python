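from datetime import datetime, timedelta

import numpy as np
import pytest

from affectcast.lexicon import BASIC_EMOTIONS, Lexicon
from affectcast.scoring import MessageRecord


@pytest.fixture(scope="session")
def lexicon() -> Lexicon:
    """Small six-emotion lexicon with 20 words per category."""
    pairs = [(f"{cat}w{i:02d}", cat) for cat in BASIC_EMOTIONS for i in range(20)]
    pairs.append(("bittersweet", "joy"))
    pairs.append(("bittersweet", "sadness"))  # multi-category word
    return Lexicon.from_pairs(pairs, categories=BASIC_EMOTIONS)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_message(user="u1", day=0, text="hello world", hour=12):
    return MessageRecord(
        user, datetime(2011, 3, 7) + timedelta(days=day, hours=hour), text
    )


@pytest.fixture
def message_factory():
    return make_message
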