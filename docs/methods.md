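# Methods

## Problem and pipeline

The package quantifies the *dynamics* of emotional expression in a
person's social-media posting stream and relates them to depression
symptom severity (PHQ-9 total, 0–27, one administration per person). The
pipeline is: read posts or per-post counts → apply inclusion rules →
score text against an emotion lexicon → per-post proportions → per-person
dynamics features → rank-based association with severity.

The unit of observation is one status update; the unit of analysis is one
participant. All timestamps are held internally as fractional minutes
since the Unix epoch at one-second resolution, so inter-post intervals are
naturally in minutes and recording periods in days are `minutes / 1440`.

## Lexicon scoring

A lexicon maps categories (at minimum `posemo`, `negemo`) to entries that
are either literal tokens or wildcard stems with one trailing `*`
(prefix match). Tokenization lowercases, splits on whitespace, and strips
leading/trailing punctuation from tokens containing letters or digits;
tokens made entirely of punctuation/symbols (emoticons, emoji) are kept
verbatim so they can match lexicon entries. A token matching entries in
both categories increments both counts; each token counts at most once per
category. Per-post proportion = category count / total tokens.

Numerical edge cases: a zero-word post has no defined proportion and is
excluded from the emotion series (counted and logged); posting-time
features still use its timestamp, since it is a real posting event.

The shipped dictionary (`emodyn/_data/toy_lexicon.dic`, ~40 entries per
category including stems and emoticons) is a structural stand-in: the
LIWC 2007 emotion dictionaries this format mirrors are proprietary and
cannot be redistributed. Users can point `--lexicon` at a licensed `.dic`
file and merge an emoji/slang supplement.

## Dynamics features

For proportions `x_1..x_n` at times `t_1..t_n`:

- mean: arithmetic average.
- iSD: standard deviation with the sample (n−1) denominator by default.
  Whether the original within-person SD convention used n or n−1 is not
  determinable for every published use of the statistic, so `ddof` is an
  argument; n−1 follows common experience-sampling practice.
- MSSD: `mean((x_{i+1} − x_i)^2)` over the n−1 successive pairs.
- time-adjusted MSSD: weights `w_i = median(Δt) / Δt_i` applied to each
  squared difference, averaged over the n−1 pairs. The median gap is
  computed per participant, never pooled across people. Because the
  weights are ratios of durations, the statistic is invariant to rescaling
  all timestamps by a positive constant, and reduces exactly to the MSSD
  under equal spacing.
- lag-1 autocorrelation (inertia): Pearson correlation of `x[:-1]` with
  `x[1:]`, spacing-ignored; exploratory only, since irregular gaps make a
  single "lag" heterogeneous.

Zero gaps (same-second posts) are floored to one second before weighting;
this reflects timestamp resolution rather than true simultaneity and keeps
`w_i` finite. A series whose timestamps are all identical has no usable
time structure and yields a missing value. Features requiring n ≥ 2 (iSD,
MSSD, taMSSD) or n ≥ 3 (autocorrelation) are reported missing below those
sizes and drop out of correlations pairwise.

## Inclusion rules

Defaults: reposts/retweets dropped; posts outside the window
`[severity_time − 365 days, severity_time]` dropped (the 12-month lookback
is implemented as 365 days, inclusive); participants kept only with ≥ 10
remaining posts spanning ≥ 7 days. The 7-day span is measured first-to-last
retained post (the alternative — first post to assessment — is a
sensitivity variant users can emulate by adjusting thresholds). Equal post
counts on both platforms allocate to Facebook; no principled tie-break
exists and the choice is logged. Filtering is idempotent and conserves
counts: input = reposts removed + out-of-window removed + retained, per
participant.

## Rank-based inference

- Spearman rho = Pearson correlation of average-ranked data; two-tailed p
  from `t = r·sqrt((n−2)/(1−r²))` with n−2 df; 95% CI by Fisher z with
  standard error `1/sqrt(n−3)`. The CI method is a standard choice for
  rank correlations; a bootstrap would be a reasonable alternative but the
  z-interval is what the package reports.
- Partial Spearman = partial Pearson on ranks: every variable is
  rank-transformed, the two focal variables are residualized on the
  controls (least squares with intercept), and the residuals are
  correlated; df = n − 2 − k, CI standard error `1/sqrt(n−3−k)`. Collinear
  controls raise an error naming the offending set. If the controls
  explain a focal variable exactly (zero residual variance), the partial
  coefficient is reported as 0 with p = 1 — there is no remaining
  association to estimate — while zero rank variance in a raw input is
  reported as missing.
- Mann–Whitney U is reported for the first sample
  (`U₁ = R₁ − n₁(n₁+1)/2`). The two-tailed p is exact by full enumeration
  of rank assignments when `n₁+n₂ ≤ 12` with no ties, otherwise a normal
  approximation with tie correction and continuity correction.
- No multiple-testing correction is applied by default (alpha .05,
  two-tailed throughout); tables report per-row n under pairwise deletion.

## Synthetic cohorts

The generator exists so the full pipeline can be exercised, and its
recovery behaviour quantified, without access to any real posting data.
Per participant: severity from a truncated normal on 0..27 (resampled
until in range, then rounded); post count `n ~ Poisson(posts_mean·f)`
clamped to ≥ 12; log-normal inter-post gaps in minutes with log-scale
reduced by `ln(f)`, where `f = 1 + beta_posting·severity/27` is the
posting-rate coupling — scaling counts up and gaps down together raises
posts-per-day and shortens median intervals for severe participants while
keeping recording periods comparable. The severity assessment falls one
further gap after the last post.

The latent negative-emotion process is a stationary AR(1) with marginal SD
σ and lag-1 correlation φ, with

- φ = `phi0 − beta_instability·severity/27` (instability coupling:
  expected MSSD of a stationary AR(1) is `2σ²(1−φ)`, so lower φ at fixed σ
  means larger successive swings with unchanged dispersion), and
- σ = `max(0.005, sigma_neg − beta_variability·severity/27)` (variability
  coupling at fixed φ).

Holding marginal variance fixed while φ moves is the minimal construction
that dissociates instability from variability. Proportions are
`clip(baseline + z_t, 0, 1)`; the positive channel is an independent AR(1)
with fixed parameters. Counts mode draws `n_words ~ 5 + Poisson(10)` and
rounds `p_t·n_words`; text mode realizes those counts as actual lexicon
tokens plus neutral filler, so scoring the text through the same lexicon
reproduces the counts exactly (the round-trip property). Cohorts draw each
participant from an independent spawned substream of one root seed, so
output is reproducible and participants are mutually independent.

### Preset parameters and why

The `facebook` preset couples severity to instability and posting rate
(baseline negative proportion 0.04, positive 0.095, severity mean 11.48,
SD 6.38, median gap ≈ 3800 min); the `twitter` preset couples severity to
*lower* variability (baseline negative 0.09, positive 0.074, severity
9.80/6.81, median gap ≈ 1000 min); the `null` preset has no couplings and
is used for type-I-error calibration.

Two generator choices deserve explanation. First, the negative-channel
marginal SD (0.07 for the Facebook preset) implies that roughly a quarter
of latent draws clip at zero. This is deliberate: real negative-emotion
proportions are heavily zero-inflated (most posts contain no negative
emotion words), and integer word counts at ~15 words per post quantize
per-post proportions coarsely, so a much smaller latent SD would disappear
into rounding noise. Second, the preset expects ~30 posts per participant;
instability estimates from successive differences are noisy, and this
stream length makes per-person taMSSD stable enough for cohort-level
couplings of realistic magnitude to be recovered reliably at 200
participants, with resulting correlations (ρ ≈ 0.25–0.45 for the
instability coupling; ≈ +0.55/−0.5 for the posting couplings) of the same
order as published platform findings. Clipping at extreme parameters
biases moments; at the shipped defaults the quantization, not the
clipping, dominates the measurement noise.

### What the generator does not emulate

AR(1) latent dynamics, log-normal gaps, and severity constant in time are
modelling conveniences: real posting streams show event-driven reactivity,
diurnal and seasonal cycles, mood-congruent content selection, and
within-person severity drift, none of which are modelled. Passing recovery
tests therefore demonstrates that the *pipeline* measures what it claims
on data whose generating process is known — not that real platform data
satisfy these assumptions.

## Problem sizes

The test suite and acceptance script use cohorts of 200 participants
(single cohorts and 20-seed batteries), 200 replicate null cohorts of 50
participants for calibration, and n = 10⁵ series for the AR(1) closed-form
check; formula-level oracle comparisons use 100 random fixtures of 2–50
observations. These sizes give stable pass/fail behaviour for the
properties being checked while keeping a full run in the tens of seconds.

## Known limitations

- Lexicon scoring is closed-vocabulary: no negation handling, sarcasm, or
  embedding-based sentiment; LIWC 2015-style categories are out of scope.
- The taMSSD weighting is one defensible choice for irregular sampling;
  model-based alternatives (continuous-time Ornstein–Uhlenbeck fits) are
  not implemented.
- The Fisher-z CI for partial rank correlations is approximate at small n.
- Hyphenated compounds count as one token; platform-specific tokenization
  (hashtags, mentions) is not special-cased.
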