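"""Per-participant emotion-dynamics features.

Given a participant's per-post emotion-word proportions x_1..x_n observed at
times t_1..t_n (minutes), this module computes:

* the average proportion, mean(x);
* within-person variability, the individual standard deviation
  iSD = sqrt(sum((x_i - mean(x))^2) / (n - 1));
* instability, the mean squared successive difference
  MSSD = mean_i (x_{i+1} - x_i)^2;
* the time-adjusted MSSD for irregular sampling,
  taMSSD = mean_i [ median(dt) / dt_i ] * (x_{i+1} - x_i)^2,
  which up-weights successive pairs closer together than the participant's
  median inter-post gap and reduces exactly to the MSSD under equal spacing;
* exploratory lag-1 autocorrelation (emotional inertia);
* posting-frequency features (posts per day, median inter-post interval in
  minutes, recording period in days up to the severity administration).

Same-second posts produce zero gaps; those are floored to one second before
weighting so the taMSSD weight stays finite (timestamp resolution, not true
simultaneity).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .ingest import MINUTES_PER_DAY, ParticipantSeries
from .lexicon import EmotionLexicon, score_post

log = logging.getLogger(__name__)

#: minimum inter-post gap, in minutes (= 1 second), used for taMSSD weights
ZERO_GAP_FLOOR = 1.0 / 60.0


@dataclass(frozen=True)
class EmotionSeries:
    """One participant's proportion series for one emotion category."""

    values: np.ndarray  # proportions in [0, 1], time order
    times: np.ndarray  # minutes, non-decreasing

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "times", times)
        if values.shape != times.shape or values.ndim != 1:
            raise ValueError("values and times must be 1-D arrays of equal length")
        if values.size == 0:
            raise ValueError("series must contain at least one observation")
        if np.any(np.diff(times) < 0):
            raise ValueError("times must be non-decreasing")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def dt(self) -> np.ndarray:
        """Successive time increments t_{i+1} - t_i (minutes)."""
        return np.diff(self.times)

    @property
    def median_dt(self) -> float:
        """Median inter-observation gap; defined only for n >= 2."""
        if self.n < 2:
            raise ValueError("median_dt requires at least two observations")
        return float(np.median(self.dt))


def _values(series) -> np.ndarray:
    if isinstance(series, EmotionSeries):
        return series.values
    return np.asarray(series, dtype=float)


def mean_proportion(series) -> float:
    """Average of the per-post proportions."""
    x = _values(series)
    if x.size == 0:
        raise ValueError("empty series")
    return float(np.mean(x))


def isd(series, ddof: int = 1) -> float:
    """Within-person variability: standard deviation of the proportions.

    Sample SD (denominator n-1) by default; ``ddof=0`` gives the population
    form. Undefined (NaN) for fewer than two observations.
    """
    x = _values(series)
    if x.size - ddof < 1:
        return math.nan
    return float(np.std(x, ddof=ddof))


def mssd(series) -> float:
    """Mean squared successive difference over the time-ordered values."""
    x = _values(series)
    if x.size < 2:
        return math.nan
    return float(np.mean(np.diff(x) ** 2))


def time_adjusted_mssd(series: EmotionSeries, times=None) -> float:
    """MSSD with each squared difference weighted by median(dt)/dt_i.

    Accepts an :class:`EmotionSeries` or ``(values, times)``. Weights depend
    only on gap ratios, so rescaling all timestamps by a positive constant
    leaves the result unchanged. All-identical timestamps give NaN.
    """
    if not isinstance(series, EmotionSeries):
        series = EmotionSeries(values=np.asarray(series, float), times=np.asarray(times, float))
    if series.n < 2:
        return math.nan
    gaps = series.dt
    if np.all(gaps == 0):
        log.warning("all timestamps identical; time-adjusted MSSD undefined")
        return math.nan
    gaps = np.maximum(gaps, ZERO_GAP_FLOOR)
    weights = np.median(gaps) / gaps
    return float(np.mean(weights * np.diff(series.values) ** 2))


def autocorrelation(series) -> float:
    """Lag-1 Pearson autocorrelation of the time-ordered values (inertia).

    Spacing-ignored, exploratory. NaN when n < 3 or either lagged slice has
    zero variance.
    """
    x = _values(series)
    if x.size < 3:
        return math.nan
    a, b = x[:-1], x[1:]
    if np.std(a) == 0 or np.std(b) == 0:
        return math.nan
    return float(np.corrcoef(a, b)[0, 1])


class PostingFeatures(NamedTuple):
    posts_per_day: float
    median_interval_min: float
    recording_period_days: float


def posting_features(series: ParticipantSeries) -> PostingFeatures:
    """Posting-frequency descriptives for one participant.

    The recording period runs from the first collected post to the severity
    administration; posts per day is the post count over that period; the
    interval feature is the participant's median gap between posts, minutes.
    """
    times = series.times()
    if times.size < 2:
        return PostingFeatures(math.nan, math.nan, math.nan)
    if series.severity_time is None:
        raise ValueError("posting features require a severity administration time")
    period_days = (series.severity_time - times[0]) / MINUTES_PER_DAY
    if period_days <= 0:
        log.warning("%s: zero-length recording period", series.participant_id)
        return PostingFeatures(math.nan, float(np.median(np.diff(times))), math.nan)
    return PostingFeatures(
        posts_per_day=times.size / period_days,
        median_interval_min=float(np.median(np.diff(times))),
        recording_period_days=float(period_days),
    )


@dataclass(frozen=True)
class DynamicsFeatures:
    """Per-participant feature row: emotion dynamics + posting frequency."""

    participant_id: str
    platform: str
    severity: int
    n_posts: int
    n_zero_word: int
    mean_pos: float
    mean_neg: float
    isd_pos: float
    isd_neg: float
    mssd_pos: float
    mssd_neg: float
    tamssd_pos: float
    tamssd_neg: float
    autocorr_pos: float
    autocorr_neg: float
    posts_per_day: float
    median_interval_min: float
    recording_period_days: float


FEATURE_COLUMNS = [
    "mean_pos", "mean_neg", "isd_pos", "isd_neg", "mssd_pos", "mssd_neg",
    "tamssd_pos", "tamssd_neg", "autocorr_pos", "autocorr_neg",
    "posts_per_day", "median_interval_min", "recording_period_days",
]


def emotion_series(series: ParticipantSeries, category: str) -> EmotionSeries:
    """Extract one category's proportion series, dropping zero-word posts."""
    usable = [s for s in series.summaries if s.n_words > 0]
    if not usable:
        raise ValueError(f"{series.participant_id}: no posts with words")
    counts = {"pos": "n_pos", "neg": "n_neg"}[category]
    values = np.array([getattr(s, counts) / s.n_words for s in usable])
    times = np.array([s.timestamp for s in usable])
    return EmotionSeries(values=values, times=times)


def compute_features(series: ParticipantSeries, isd_ddof: int = 1) -> DynamicsFeatures:
    """All dynamics features for one participant.

    Posting features use every post's timestamp; the emotion series exclude
    zero-word posts, whose proportion is undefined (the exclusion count is
    reported).
    """
    n_zero = sum(1 for s in series.summaries if s.n_words == 0)
    if n_zero:
        log.info("%s: %d zero-word posts excluded from emotion series",
                 series.participant_id, n_zero)
    out: dict[str, float] = {}
    for cat in ("pos", "neg"):
        es = emotion_series(series, cat)
        out[f"mean_{cat}"] = mean_proportion(es)
        out[f"isd_{cat}"] = isd(es, ddof=isd_ddof)
        out[f"mssd_{cat}"] = mssd(es)
        out[f"tamssd_{cat}"] = time_adjusted_mssd(es)
        out[f"autocorr_{cat}"] = autocorrelation(es)
    posting = posting_features(series)
    return DynamicsFeatures(
        participant_id=series.participant_id,
        platform=series.platform,
        severity=series.severity,
        n_posts=series.n_posts,
        n_zero_word=n_zero,
        posts_per_day=posting.posts_per_day,
        median_interval_min=posting.median_interval_min,
        recording_period_days=posting.recording_period_days,
        **out,
    )


def features_table(
    series_set: Sequence[ParticipantSeries],
    isd_ddof: int = 1,
) -> pd.DataFrame:
    """Feature rows for a cohort, one participant per row."""
    rows = [vars(compute_features(s, isd_ddof=isd_ddof)) for s in series_set]
    columns = ["participant_id", "platform", "severity", "n_posts", "n_zero_word",
               *FEATURE_COLUMNS]
    return pd.DataFrame(rows, columns=columns)


def score_series(series_posts, lexicon: EmotionLexicon, severity: int,
                 severity_time: float | None) -> ParticipantSeries:
    """Text path: score raw posts through the lexicon, then build the series."""
    from .ingest import build_series

    summaries = [score_post(p, lexicon) for p in series_posts]
    return build_series(summaries, severity=severity, severity_time=severity_time)
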