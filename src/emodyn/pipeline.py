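"""End-to-end orchestration: files in, feature and association tables out.

The command-line interface is a thin layer over these functions; they are
equally usable from a notebook or script.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path

import pandas as pd

from . import association, dynamics, ingest, lexicon as lexmod

log = logging.getLogger(__name__)

DEFAULT_FEATURES = ["mean_pos", "mean_neg", "isd_pos", "isd_neg",
                    "tamssd_pos", "tamssd_neg"]


def load_lexicon(path=None, supplement=None) -> lexmod.EmotionLexicon:
    lex = lexmod.load_dic(path) if path else lexmod.toy_lexicon()
    if supplement:
        lexmod.load_supplement(supplement, lex)
    return lex


def score_posts_file(posts_path, out_path, lexicon_path=None, supplement=None,
                     fmt: str = "jsonl") -> pd.DataFrame:
    """Score raw text posts through the lexicon; write the counts CSV."""
    lex = load_lexicon(lexicon_path, supplement)
    result = ingest.read_posts(posts_path, fmt=fmt)
    if result.n_errors:
        log.warning("%d malformed post records skipped", result.n_errors)
    rows = []
    for post in result.records:
        s = lexmod.score_post(post, lex)
        rows.append({
            "participant_id": s.participant_id,
            "timestamp": ingest.format_timestamp(s.timestamp),
            "n_words": s.n_words, "n_pos": s.n_pos, "n_neg": s.n_neg,
            "platform": s.platform, "is_repost": s.is_repost,
        })
    frame = pd.DataFrame(
        rows, columns=["participant_id", "timestamp", "n_words", "n_pos",
                       "n_neg", "platform", "is_repost"],
    )
    if out_path:
        frame.to_csv(out_path, index=False)
    return frame


def assemble_series(
    summaries: list[ingest.PostSummary],
    severity: dict[str, tuple[int, float]],
) -> list[ingest.ParticipantSeries]:
    """Group summaries by participant, allocate dual-platform users, build series.

    Participants with posts on both platforms keep only their larger
    platform's series. Participants without a severity record are kept with
    ``severity_time=None`` so the inclusion filter can report them.
    """
    by_participant: dict[str, dict[str, list[ingest.PostSummary]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for s in summaries:
        by_participant[s.participant_id][s.platform].append(s)
    out = []
    for pid in sorted(by_participant):
        platforms = by_participant[pid]
        if len(platforms) > 1:
            chosen = ingest.allocate_platform(
                {plat: len(recs) for plat, recs in platforms.items()}
            )
            log.info("%s posts on %s; allocated to %s", pid, sorted(platforms), chosen)
        else:
            chosen = next(iter(platforms))
        sev, sev_time = severity.get(pid, (0, None))
        out.append(
            ingest.build_series(
                platforms[chosen], severity=sev, severity_time=sev_time,
                participant_id=pid, platform=chosen,
            )
        )
    return out


def features_from_files(
    summaries_path,
    severity_path,
    outdir,
    min_posts: int = 10,
    min_span_days: float = 7.0,
    max_lookback_days: float = 365.0,
    exclude_reposts: bool = True,
    isd_ddof: int = 1,
) -> pd.DataFrame:
    """Counts CSV + severity CSV -> per-participant features CSV + exclusion report."""
    read = ingest.read_summaries(summaries_path)
    if read.n_errors:
        log.warning("%d malformed summary records skipped", read.n_errors)
    severity = ingest.read_severity(severity_path)
    series_set = assemble_series(read.records, severity)
    included, report = ingest.apply_inclusion_criteria(
        series_set, min_posts=min_posts, min_span_days=min_span_days,
        max_lookback_days=max_lookback_days, exclude_reposts=exclude_reposts,
    )
    if not included:
        raise RuntimeError("no participant passes the inclusion criteria")
    frame = dynamics.features_table(included, isd_ddof=isd_ddof)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(outdir / "features.csv", index=False)
    report.write_csv(outdir / "exclusions.csv")
    log.info("features written for %d participants (%d excluded)",
             len(frame), len(report.excluded))
    return frame


def associate_from_features(
    features: pd.DataFrame,
    feature_list=None,
    control_sets=((),),
    out_path=None,
) -> pd.DataFrame:
    """Per-platform severity correlations for the configured features."""
    feature_list = feature_list or DEFAULT_FEATURES
    frames = []
    for platform, sub in features.groupby("platform"):
        table = association.association_table(sub, feature_list, control_sets)
        table.insert(0, "platform", platform)
        frames.append(table)
    result = pd.concat(frames, ignore_index=True)
    if out_path:
        result.to_csv(out_path, index=False)
    return result


def read_flat_config(path) -> dict[str, str]:
    """Flat ``key=value`` config file; '#' comments and blank lines ignored."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path} line {lineno}: expected key=value")
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out
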