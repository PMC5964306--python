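"""Synthetic posting-stream cohorts with known ground-truth emotion dynamics.

Each participant is generated as:

1. a PHQ-9 severity total from a truncated normal on 0..27, rounded;
2. a post count n ~ Poisson(posts_mean * (1 + beta_posting * severity/27)),
   clamped to at least 12 so every participant can clear the inclusion rules;
3. log-normal inter-post gaps (minutes) whose scale shrinks by the same
   posting-coupling factor, cumulated into timestamps at one-second
   resolution, with the severity administration after the last post; scaling
   both the count up and the gaps down makes higher-severity participants
   post more often per day at shorter median intervals while keeping the
   recording period comparable;
4. a latent stationary AR(1) process z_t for the negative channel with lag-1
   correlation phi = phi0 - beta_instability * severity/27 and marginal SD
   sigma = max(0.005, sigma_neg - beta_variability * severity/27); holding
   the marginal variance fixed while phi moves isolates *instability* (the
   expected MSSD of a stationary AR(1) is 2 sigma^2 (1 - phi)) from
   *variability* (iSD estimates sigma). The positive channel is an
   independent AR(1) with fixed parameters;
5. per-post proportions p_t = clip(baseline + z_t, 0, 1), then counts
   n_words ~ 5 + Poisson(10) and n_cat = round(p_t * n_words); in text mode
   the counts are realized as actual lexicon tokens plus neutral filler, so
   scoring the text through the same lexicon reproduces the intended counts
   exactly.

Participants are generated from independent seeded substreams of one root
seed sequence, so cohorts are reproducible and one participant's data does
not depend on any other's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import ParticipantSeries, Post, PostSummary, format_timestamp, parse_timestamp

log = logging.getLogger(__name__)

#: first possible post time for generated cohorts
EPOCH_START = parse_timestamp("2017-01-01T00:00:00Z")

#: tokens realized in text mode; each must score exactly one category
POS_POOL = ("happy", "joy", "love", "great", "awesome", "wonderful", "grateful",
            "laughing", "proud", "yay", ":)", "=)")
NEG_POOL = ("sad", "miserable", "crying", "awful", "terrible", "angry", "upset",
            "anxious", "lonely", "ugh", ":(", ":'(")
#: neutral vocabulary; must match no toy-lexicon entry, literal or stem
FILLER_POOL = ("today", "went", "to", "the", "market", "and", "then", "home",
               "watched", "a", "movie", "with", "friends", "coffee", "this",
               "morning", "later", "maybe", "weekend", "work", "meeting",
               "about", "new", "project", "dinner", "was", "ready", "early")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; presets mirror the two platform samples."""

    n_participants: int = 200
    platform: str = "facebook"
    severity_mean: float = 11.48
    severity_sd: float = 6.38
    posts_mean: float = 30.0
    interval_log_mean: float = 8.25  # ln(minutes); exp(8.25) ~ 3800 min
    interval_log_sd: float = 1.0
    baseline_neg: float = 0.04
    baseline_pos: float = 0.095
    sigma_neg: float = 0.07
    sigma_pos: float = 0.05
    phi0: float = 0.05
    phi_pos: float = 0.2
    beta_instability: float = 0.0
    beta_variability: float = 0.0
    beta_posting: float = 0.0
    seed: int = 0
    mode: str = "counts"

    def phi_neg(self, severity: int) -> float:
        return self.phi0 - self.beta_instability * severity / 27.0

    def marginal_sigma_neg(self, severity: int) -> float:
        return max(0.005, self.sigma_neg - self.beta_variability * severity / 27.0)

    def validate(self) -> None:
        if self.mode not in ("counts", "text"):
            raise ValueError(f"mode must be 'counts' or 'text', got {self.mode!r}")
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        for name in ("severity_sd", "interval_log_sd", "sigma_neg", "sigma_pos",
                     "beta_instability", "beta_variability"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(self.phi0) + abs(self.beta_instability) >= 1:
            raise ValueError("|phi0| + |beta_instability| must be < 1 so the lag-1 "
                             "correlation stays in (-1, 1) at every severity")
        for sev in (0, 27):
            if not (-1 < self.phi_neg(sev) < 1):
                raise ValueError(f"phi at severity {sev} is outside (-1, 1)")
            if self.marginal_sigma_neg(sev) <= 0:
                raise ValueError(f"sigma at severity {sev} is not positive")
        if not (-1 < self.phi_pos < 1):
            raise ValueError("phi_pos must be in (-1, 1)")


def facebook_preset(**overrides) -> SyntheticConfig:
    """Severity-coupled *instability* plus posting-rate coupling.

    Baselines follow the Facebook sample descriptives (negative proportion
    ~0.04, positive ~0.095, a ~3800-minute median inter-post gap, recording
    periods of a few months). Severity lowers the lag-1 autocorrelation of
    the latent negative process from 0.05 to -0.85 at fixed marginal SD, so
    higher severity means larger swings between consecutive posts but an
    unchanged overall dispersion.
    """
    cfg = SyntheticConfig(
        platform="facebook",
        severity_mean=11.48, severity_sd=6.38,
        posts_mean=30.0, interval_log_mean=8.25, interval_log_sd=1.0,
        baseline_neg=0.04, baseline_pos=0.095,
        sigma_neg=0.07, sigma_pos=0.05,
        phi0=0.05, beta_instability=0.9, beta_variability=0.0, beta_posting=1.0,
    )
    return replace(cfg, **overrides)


def twitter_preset(**overrides) -> SyntheticConfig:
    """Severity-coupled *variability* (higher severity, smaller marginal SD).

    Baselines follow the Twitter sample descriptives (negative proportion
    ~0.09, positive ~0.074, ~27 posts at a ~1000-minute median gap).
    """
    cfg = SyntheticConfig(
        platform="twitter",
        severity_mean=9.80, severity_sd=6.81,
        posts_mean=26.90, interval_log_mean=6.94, interval_log_sd=1.6,
        baseline_neg=0.09, baseline_pos=0.074,
        sigma_neg=0.03, sigma_pos=0.02,
        phi0=0.2, beta_instability=0.0, beta_variability=0.02, beta_posting=0.0,
    )
    return replace(cfg, **overrides)


def null_preset(**overrides) -> SyntheticConfig:
    """No severity coupling at all; for type-I-error calibration."""
    cfg = facebook_preset(beta_instability=0.0, beta_variability=0.0, beta_posting=0.0)
    return replace(cfg, **overrides)


PRESETS = {"facebook": facebook_preset, "twitter": twitter_preset, "null": null_preset}


@dataclass
class GroundTruth:
    """What the generator intended for one participant."""

    participant_id: str
    severity: int
    phi_neg: float
    sigma_neg: float
    p_neg: np.ndarray
    p_pos: np.ndarray
    n_words: np.ndarray
    n_neg: np.ndarray
    n_pos: np.ndarray
    texts: list[str] | None = None


def _ar1(n: int, phi: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) with marginal SD sigma and lag-1 correlation phi."""
    z = np.empty(n)
    z[0] = rng.normal(0.0, sigma)
    innov_sd = sigma * np.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        z[i] = phi * z[i - 1] + eps[i - 1]
    return z


def _truncated_severity(config: SyntheticConfig, rng: np.random.Generator) -> int:
    for _ in range(1000):
        draw = rng.normal(config.severity_mean, config.severity_sd)
        if 0 <= draw <= 27:
            return int(round(draw))
    raise RuntimeError("severity truncation failed; check severity_mean/severity_sd")


def _realize_text(n_words: int, n_pos: int, n_neg: int,
                  rng: np.random.Generator) -> str:
    tokens = list(rng.choice(POS_POOL, size=n_pos))
    tokens += list(rng.choice(NEG_POOL, size=n_neg))
    tokens += list(rng.choice(FILLER_POOL, size=n_words - n_pos - n_neg))
    order = rng.permutation(len(tokens))
    return " ".join(tokens[i] for i in order)


def generate_participant(
    severity: int,
    config: SyntheticConfig,
    rng: np.random.Generator,
    participant_id: str = "p1",
    posting_factor: float = 1.0,
) -> tuple[ParticipantSeries, GroundTruth]:
    """One participant's posting stream, counts, and ground truth.

    ``posting_factor`` (>= 1) multiplies the expected post count and divides
    the inter-post gap scale; :func:`generate_cohort` sets it from the
    posting-rate coupling.
    """
    config.validate()
    n = max(12, int(rng.poisson(config.posts_mean * posting_factor)))
    gap_log_mean = config.interval_log_mean - np.log(posting_factor)
    gaps = rng.lognormal(gap_log_mean, config.interval_log_sd, size=n)
    times = EPOCH_START + np.cumsum(gaps)
    times = np.round(times * 60.0) / 60.0  # one-second resolution
    severity_time = float(
        np.round((times[-1] + rng.lognormal(gap_log_mean,
                                            config.interval_log_sd)) * 60.0) / 60.0
    )
    phi = config.phi_neg(severity)
    sigma = config.marginal_sigma_neg(severity)
    z_neg = _ar1(n, phi, sigma, rng)
    z_pos = _ar1(n, config.phi_pos, config.sigma_pos, rng)
    p_neg = np.clip(config.baseline_neg + z_neg, 0.0, 1.0)
    p_pos = np.clip(config.baseline_pos + z_pos, 0.0, 1.0)
    n_words = 5 + rng.poisson(10, size=n)
    n_neg = np.minimum(np.round(p_neg * n_words).astype(int), n_words)
    n_pos = np.minimum(np.round(p_pos * n_words).astype(int), n_words - n_neg)
    texts: list[str] | None = None
    if config.mode == "text":
        texts = [
            _realize_text(int(w), int(np_), int(nn), rng)
            for w, np_, nn in zip(n_words, n_pos, n_neg)
        ]
    summaries = [
        PostSummary(
            participant_id=participant_id, timestamp=float(t),
            n_words=int(w), n_pos=int(np_), n_neg=int(nn),
            platform=config.platform,
        )
        for t, w, np_, nn in zip(times, n_words, n_pos, n_neg)
    ]
    series = ParticipantSeries(
        participant_id=participant_id, platform=config.platform,
        summaries=summaries, severity=severity, severity_time=severity_time,
    )
    truth = GroundTruth(
        participant_id=participant_id, severity=severity, phi_neg=phi,
        sigma_neg=sigma, p_neg=p_neg, p_pos=p_pos, n_words=n_words,
        n_neg=n_neg, n_pos=n_pos, texts=texts,
    )
    return series, truth


@dataclass
class Cohort:
    config: SyntheticConfig
    series: list[ParticipantSeries]
    truths: list[GroundTruth]

    def severity_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [s.participant_id for s in self.series],
                "phq9_total": [s.severity for s in self.series],
                "administered_at": [format_timestamp(s.severity_time) for s in self.series],
            }
        )

    def summaries_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.series:
            for summ in s.summaries:
                rows.append(
                    {
                        "participant_id": summ.participant_id,
                        "timestamp": format_timestamp(summ.timestamp),
                        "n_words": summ.n_words,
                        "n_pos": summ.n_pos,
                        "n_neg": summ.n_neg,
                        "platform": summ.platform,
                        "is_repost": summ.is_repost,
                    }
                )
        return pd.DataFrame(rows)

    def posts(self) -> list[Post]:
        if self.config.mode != "text":
            raise ValueError("posts are only realized in text mode")
        out = []
        for series, truth in zip(self.series, self.truths):
            assert truth.texts is not None
            for summ, text in zip(series.summaries, truth.texts):
                out.append(
                    Post(
                        participant_id=summ.participant_id,
                        timestamp=summ.timestamp, text=text,
                        platform=summ.platform, is_repost=summ.is_repost,
                    )
                )
        return out

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [t.participant_id for t in self.truths],
                "severity": [t.severity for t in self.truths],
                "phi_neg": [t.phi_neg for t in self.truths],
                "sigma_neg": [t.sigma_neg for t in self.truths],
                "n_posts": [t.n_words.size for t in self.truths],
            }
        )

    def write(self, outdir) -> dict[str, Path]:
        """Write summaries (and posts in text mode), severity, ground truth, config."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["summaries"] = outdir / "summaries.csv"
        self.summaries_frame().to_csv(paths["summaries"], index=False)
        paths["severity"] = outdir / "severity.csv"
        self.severity_frame().to_csv(paths["severity"], index=False)
        paths["ground_truth"] = outdir / "ground_truth.csv"
        self.truth_frame().to_csv(paths["ground_truth"], index=False)
        if self.config.mode == "text":
            import json

            paths["posts"] = outdir / "posts.jsonl"
            with open(paths["posts"], "w", encoding="utf-8") as fh:
                for post in self.posts():
                    fh.write(json.dumps({
                        "participant_id": post.participant_id,
                        "timestamp": format_timestamp(post.timestamp),
                        "text": post.text,
                        "platform": post.platform,
                        "is_repost": post.is_repost,
                    }) + "\n")
        paths["config"] = outdir / "config.txt"
        with open(paths["config"], "w", encoding="utf-8") as fh:
            for key, value in asdict(self.config).items():
                fh.write(f"{key}={value}\n")
        return paths


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """A cohort of independent participants from one seeded root generator.

    Participant i always draws from the i-th spawned substream, so the data
    are reproducible and substreams are mutually independent.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_participants)
    series_list: list[ParticipantSeries] = []
    truths: list[GroundTruth] = []
    width = len(str(config.n_participants))
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        severity = _truncated_severity(config, rng)
        factor = 1.0 + config.beta_posting * severity / 27.0
        pid = f"p{i + 1:0{width}d}"
        series, truth = generate_participant(
            severity, config, rng, participant_id=pid, posting_factor=factor
        )
        series_list.append(series)
        truths.append(truth)
    log.info("generated %d participants (%s preset-like config, mode=%s)",
             config.n_participants, config.platform, config.mode)
    return Cohort(config=config, series=series_list, truths=truths)
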