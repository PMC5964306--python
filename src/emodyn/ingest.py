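"""Reading post streams, inclusion filtering, and per-participant series assembly.

Timestamps are held internally as fractional **minutes since the Unix
epoch** (UTC) at one-second resolution; inter-post intervals are therefore
in minutes, the unit in which posting descriptives are reported.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440.0

PLATFORMS = ("facebook", "twitter")


def parse_timestamp(value: str) -> float:
    """Parse an ISO-8601 timestamp to minutes since the Unix epoch (UTC).

    Raises ValueError for anything pandas cannot parse unambiguously.
    """
    ts = pd.Timestamp(value)
    if ts is pd.NaT:
        raise ValueError(f"unparseable timestamp: {value!r}")
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    else:
        ts = ts.tz_convert("UTC")
    return ts.value / 60e9


def format_timestamp(minutes: float) -> str:
    """Render minutes-since-epoch back to an ISO-8601 UTC string (1 s resolution)."""
    ts = pd.Timestamp(round(minutes * 60), unit="s", tz="UTC")
    return ts.strftime("%Y-%m-%dT%H:%M:%SZ")


@dataclass(frozen=True)
class Post:
    """One raw status update."""

    participant_id: str
    timestamp: float  # minutes since epoch
    text: str
    platform: str
    is_repost: bool = False

    def __post_init__(self) -> None:
        if not self.participant_id:
            raise ValueError("participant_id must be nonempty")
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform: {self.platform!r}")


@dataclass(frozen=True)
class PostSummary:
    """One status update reduced to (time, word count, emotion-word counts)."""

    participant_id: str
    timestamp: float
    n_words: int
    n_pos: int
    n_neg: int
    platform: str
    is_repost: bool = False

    def __post_init__(self) -> None:
        if not self.participant_id:
            raise ValueError("participant_id must be nonempty")
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform: {self.platform!r}")
        for name in ("n_words", "n_pos", "n_neg"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n_pos > self.n_words or self.n_neg > self.n_words:
            raise ValueError(
                f"emotion-word counts exceed word count "
                f"(n_words={self.n_words}, n_pos={self.n_pos}, n_neg={self.n_neg})"
            )


@dataclass
class ParticipantSeries:
    """Time-ordered post summaries for one participant plus their severity score.

    ``severity`` is a PHQ-9 total (0-27); ``severity_time`` is the
    administration time in minutes since epoch.
    """

    participant_id: str
    platform: str
    summaries: list[PostSummary]
    severity: int
    severity_time: float | None

    def __post_init__(self) -> None:
        if not (0 <= self.severity <= 27):
            raise ValueError(f"severity must be within [0, 27], got {self.severity}")
        times = [s.timestamp for s in self.summaries]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("summaries must be sorted by timestamp")

    @property
    def n_posts(self) -> int:
        return len(self.summaries)

    def times(self) -> np.ndarray:
        return np.array([s.timestamp for s in self.summaries], dtype=float)


@dataclass
class ReadResult:
    """Parsed records plus per-line errors for malformed input."""

    records: list
    errors: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_errors(self) -> int:
        return len(self.errors)


_POST_FIELDS = ("participant_id", "timestamp", "text", "platform")


def _post_from_mapping(rec: Mapping, lineno: int) -> Post:
    missing = [k for k in _POST_FIELDS if k not in rec or rec[k] in (None, "")]
    # empty text is legal; only id/timestamp/platform must be present
    missing = [k for k in missing if k != "text"]
    if missing:
        raise ValueError(f"missing fields {missing}")
    is_repost = rec.get("is_repost", False)
    if isinstance(is_repost, str):
        is_repost = is_repost.strip().lower() in ("1", "true", "yes")
    return Post(
        participant_id=str(rec["participant_id"]),
        timestamp=parse_timestamp(str(rec["timestamp"])),
        text=str(rec.get("text") or ""),
        platform=str(rec["platform"]).lower(),
        is_repost=bool(is_repost),
    )


def read_posts(path, fmt: str = "jsonl") -> ReadResult:
    """Read raw posts from JSONL (one object per line) or CSV.

    Malformed records are skipped and reported with their line numbers;
    an unreadable file raises.
    """
    if fmt not in ("jsonl", "csv"):
        raise ValueError(f"unknown format {fmt!r}; expected 'jsonl' or 'csv'")
    result = ReadResult(records=[])
    with open(path, encoding="utf-8") as fh:
        if fmt == "jsonl":
            rows: Iterable[tuple[int, Mapping | str]] = (
                (i, line) for i, line in enumerate(fh, start=1)
            )
            for lineno, line in rows:
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                    result.records.append(_post_from_mapping(rec, lineno))
                except (ValueError, TypeError) as exc:
                    result.errors.append((lineno, str(exc)))
                    log.warning("%s line %d: skipped (%s)", path, lineno, exc)
        else:
            reader = csv.DictReader(fh)
            for lineno, rec in enumerate(reader, start=2):
                try:
                    result.records.append(_post_from_mapping(rec, lineno))
                except (ValueError, TypeError) as exc:
                    result.errors.append((lineno, str(exc)))
                    log.warning("%s line %d: skipped (%s)", path, lineno, exc)
    if not result.records:
        log.warning("%s: no valid post records read", path)
    return result


def read_summaries(path) -> ReadResult:
    """Read pre-summarized per-post counts from CSV.

    Header: participant_id,timestamp,n_words,n_pos,n_neg,platform,is_repost
    (is_repost optional, default false).
    """
    result = ReadResult(records=[])
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for lineno, rec in enumerate(reader, start=2):
            try:
                is_repost = str(rec.get("is_repost") or "").strip().lower() in (
                    "1", "true", "yes",
                )
                result.records.append(
                    PostSummary(
                        participant_id=str(rec["participant_id"]),
                        timestamp=parse_timestamp(str(rec["timestamp"])),
                        n_words=int(rec["n_words"]),
                        n_pos=int(rec["n_pos"]),
                        n_neg=int(rec["n_neg"]),
                        platform=str(rec["platform"]).lower(),
                        is_repost=is_repost,
                    )
                )
            except (ValueError, TypeError, KeyError) as exc:
                result.errors.append((lineno, str(exc)))
                log.warning("%s line %d: skipped (%s)", path, lineno, exc)
    return result


def read_severity(path) -> dict[str, tuple[int, float]]:
    """Read PHQ-9 totals: CSV with header participant_id,phq9_total,administered_at.

    Returns {participant_id: (total, administered_at_minutes)}.
    """
    out: dict[str, tuple[int, float]] = {}
    with open(path, encoding="utf-8") as fh:
        for rec in csv.DictReader(fh):
            pid = str(rec["participant_id"])
            out[pid] = (int(rec["phq9_total"]), parse_timestamp(rec["administered_at"]))
    return out


def build_series(
    summaries: Sequence[PostSummary],
    severity: int,
    severity_time: float | None,
    participant_id: str | None = None,
    platform: str | None = None,
) -> ParticipantSeries:
    """Assemble one participant's time-ordered series.

    Summaries are stably sorted by timestamp, so same-second posts keep
    their input order. Severity outside the PHQ-9 range [0, 27] raises.
    """
    summaries = list(summaries)
    pids = {s.participant_id for s in summaries}
    if participant_id is None:
        if len(pids) != 1:
            raise ValueError(f"records span multiple participants: {sorted(pids)}")
        participant_id = next(iter(pids))
    elif pids and pids != {participant_id}:
        raise ValueError(f"records do not all belong to {participant_id!r}")
    if platform is None:
        platforms = {s.platform for s in summaries}
        if len(platforms) != 1:
            raise ValueError(f"records span multiple platforms: {sorted(platforms)}")
        platform = next(iter(platforms))
    ordered = sorted(summaries, key=lambda s: s.timestamp)  # stable
    return ParticipantSeries(
        participant_id=participant_id,
        platform=platform,
        summaries=ordered,
        severity=severity,
        severity_time=severity_time,
    )


@dataclass
class ExclusionReport:
    """Accounting of the inclusion filter.

    ``steps`` maps participant_id -> counts at each filter step;
    ``excluded`` maps participant_id -> reason for the participants dropped.
    Retained + reposts_removed + outside_window_removed == input for every
    participant (conservation).
    """

    steps: dict[str, dict[str, int]] = field(default_factory=dict)
    excluded: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"participant_id": pid, "reason": reason}
            for pid, reason in sorted(self.excluded.items())
        ]
        return pd.DataFrame(rows, columns=["participant_id", "reason"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def apply_inclusion_criteria(
    series_set: Sequence[ParticipantSeries],
    min_posts: int = 10,
    min_span_days: float = 7.0,
    max_lookback_days: float = 365.0,
    exclude_reposts: bool = True,
) -> tuple[list[ParticipantSeries], ExclusionReport]:
    """Apply the study's inclusion rules to each participant.

    Per participant: drop reposts (retweets); drop posts after the severity
    administration or more than ``max_lookback_days`` before it (inclusive
    window); keep the participant iff at least ``min_posts`` posts remain
    spanning at least ``min_span_days`` days first-to-last.
    """
    report = ExclusionReport()
    included: list[ParticipantSeries] = []
    for series in series_set:
        pid = series.participant_id
        n_in = series.n_posts
        if series.severity_time is None:
            report.steps[pid] = {
                "input": n_in, "reposts_removed": 0,
                "outside_window_removed": 0, "retained": n_in,
            }
            report.excluded[pid] = "no_reference_time"
            continue
        kept = series.summaries
        n_repost = 0
        if exclude_reposts:
            kept = [s for s in kept if not s.is_repost]
            n_repost = n_in - len(kept)
        earliest = series.severity_time - max_lookback_days * MINUTES_PER_DAY
        before = len(kept)
        kept = [s for s in kept if earliest <= s.timestamp <= series.severity_time]
        n_window = before - len(kept)
        report.steps[pid] = {
            "input": n_in,
            "reposts_removed": n_repost,
            "outside_window_removed": n_window,
            "retained": len(kept),
        }
        if len(kept) < min_posts:
            report.excluded[pid] = "too_few_posts"
            continue
        span_days = (kept[-1].timestamp - kept[0].timestamp) / MINUTES_PER_DAY
        if span_days < min_span_days:
            report.excluded[pid] = "span_too_short"
            continue
        included.append(replace(series, summaries=kept))
    log.info(
        "inclusion filter: %d of %d participants retained (%s)",
        len(included), len(series_set),
        ", ".join(f"{pid}:{r}" for pid, r in sorted(report.excluded.items())) or "none excluded",
    )
    return included, report


def allocate_platform(series_by_platform: Mapping[str, ParticipantSeries | int]) -> str:
    """Pick the platform with more posts for a dual-platform participant.

    Ties go to Facebook (logged); the study allocated all dual-platform
    users to their larger Facebook sample.
    """
    counts = {
        plat: (s if isinstance(s, int) else s.n_posts)
        for plat, s in series_by_platform.items()
    }
    best = max(counts.values())
    winners = sorted(p for p, c in counts.items() if c == best)
    if len(winners) > 1:
        log.info("platform tie %s; allocating to facebook", counts)
        return "facebook" if "facebook" in winners else winners[0]
    return winners[0]
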