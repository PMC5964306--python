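import numpy as np
import pytest

from emodyn import PostSummary, build_series, toy_lexicon

MIN_PER_DAY = 1440.0


@pytest.fixture(scope="session")
def lex():
    return toy_lexicon()


def make_summary(pid="p1", t=0.0, n_words=10, n_pos=1, n_neg=1,
                 platform="facebook", is_repost=False):
    return PostSummary(participant_id=pid, timestamp=float(t), n_words=n_words,
                       n_pos=n_pos, n_neg=n_neg, platform=platform,
                       is_repost=is_repost)


@pytest.fixture
def simple_series():
    """Ten posts, one per day, severity assessed a day after the last."""
    summaries = [make_summary(t=i * MIN_PER_DAY, n_pos=i % 3, n_neg=(i + 1) % 2)
                 for i in range(10)]
    return build_series(summaries, severity=12, severity_time=10 * MIN_PER_DAY)


def random_emotion_fixture(rng, n=None):
    """Random proportions at strictly increasing irregular times."""
    if n is None:
        n = int(rng.integers(2, 51))
    values = rng.uniform(0, 1, size=n)
    times = np.cumsum(rng.uniform(0.5, 5000.0, size=n))
    return values, times
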