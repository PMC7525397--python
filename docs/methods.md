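# Methods

`ocquery` analyses search-engine query logs for evidence about what happens
after a woman misses an oral-contraceptive (OC) dose: whether she seeks
emergency contraception in time, whether she later reports a pregnancy, and
how those outcomes differ by pill type, number of missed doses and age.
Because real search logs of this kind are proprietary, the package pairs the
analysis pipeline with a synthetic query-log generator whose defaults encode
the published cohort statistics, so every estimator can be validated by
parameter recovery.

## Query classification

Queries are assigned exactly one of five classes by keyword rules on
normalised text (lowercased, punctuation stripped except hyphens,
whitespace collapsed):

* **missed_oc** — a variant of *miss / skip / forget* together with an OC
  brand name or a generic OC term ("birth control", "contraceptive",
  "minipill"). Verb variants are matched as an explicit word-boundary
  alternation (missed/missing/skipped/forgotten/...), which avoids the
  false positives a bare prefix match would admit (e.g. "mission").
* **pregnancy_week** — "week(s)" and a pregnancy term with an attached
  integer in 1..45 ("week 21 of pregnancy", "21 weeks pregnant").
* **emergency_contraception** — "plan b" or "morning after pill".
* **miscarriage** — "after miscarriage", "post miscarriage" or
  "i had a miscarriage".
* **abortion** — "abortion".

Abortion and emergency-contraception rules carry an exclusion list
(legislation, courts, debates, news, celebrities): such queries express
public interest, not personal concern. Precedence when several rules fire is
missed_oc > pregnancy_week > emergency_contraception > miscarriage >
abortion — a missed-pill mention is the index event of interest, and a
week-of-pregnancy mention is the strongest personal signal among the rest.
Brand lists and exclusion lists live in an editable YAML-loadable lexicon;
the shipped lists are placeholders of common US brands and the cohort
statistics do not depend on their contents.

From missed-OC queries the classifier also extracts the number of missed
doses (digits or the number words one–nine within three tokens of
"pill(s)"/"dose(s)"), pill-type mentions against the combined and
progestin-only brand lists (a query can mention both), and placebo mentions
("placebo", "sugar pill").

## Timelines, gestational dating, timing

A user enters the cohort at their first missed-OC query (the *index date*).
For each follow-up class, only the first query at or after the index date
counts; gaps are in fractional days and "within 24 h" means gap < 1 day.
Same-day follow-ups count with gap 0 (for emergency contraception the
same-day case is the clinically decisive one).

Each pregnancy-week query dates the last menstrual period (LMP) as
`query date − 7·week` (start-of-reported-week convention; alternative
midpoint conventions differ by ≤ 3.5 days and are absorbed by the
generator's jitter calibration). A user's consensus LMP is the median of
the per-query estimates, kept as a possibly half-integer epoch day: taking
the lower of two central dates instead would bias the conception-day
estimate upward by about two days under symmetric dating noise. Dating
consistency is the median pairwise absolute difference between a user's LMP
estimates, and the cohort statistic is the median over users with at least
two pregnancy queries (the aggregation level is a package choice; the
alternative — pooling all pairs — moves the statistic by well under a day
on the reference scenario).

A pregnancy is *timed to the missed-pill cycle* when
`0 ≤ index − consensus LMP < 28` days (the cycle length is configurable).
For timed pregnancies the offset itself, rounded to whole days, is the
conception-day estimate: the missed-dose date is the only observable proxy
for the exposure day within the cycle, which naturally yields a dispersed
distribution.

## Censoring weights

A pregnancy conceived in October produces its pregnancy-week queries mostly
after a 2018-only window closes, so raw pregnancy rates are biased low for
late index dates. The correction estimates the empirical distribution p(k)
of reported gestational weeks over all pregnancy-week queries in the log
(not just cohort members, to maximise the sample), and weights each
missed-OC user by the observable mass

    w(t) = Σ_k p(k) · 1[t + 7k ≤ window_end],

the probability that a pregnancy-week query would still fall inside the
window given index date t. A January user has w = 1; a late-December user
can have w = 0 and is floored at ε = 0.01 so no single user dominates the
denominator. The weighted rate is (observed pregnancy reporters) / (Σ w):
a Horvitz–Thompson-style correction applied to the denominator only — an
observed pregnancy counts 1 regardless of weight. A fully inverse-weighted
variant is available behind `estimator="horvitz_thompson"` for sensitivity
analysis. "Pregnant" is operationalised as issuing ≥ 1 pregnancy-week query
at or after the index date.

Two rates are reported at cohort level: the overall weighted rate and the
non-placebo rate (missing an inactive placebo pill carries essentially no
risk, so the non-placebo cohort is the epidemiologically meaningful base).

## Other statistics

Age bands follow the reporting scheme <20, 20–24, 25–29, 30–34, 35–39, 40+,
with "under 30" the union of the first three; band comparisons default to
band vs complement among users with known age. The band contrast uses
Pearson's chi-square on the 2×2 band × has-follow-up table without
continuity correction (large-n regime; configurable). The age/dose-count
association uses Spearman's rank correlation with average ranks on ties.
Cohen's kappa (two raters, marginal-product expected agreement, kappa = 0
by convention when both raters are constant and identical) is provided for
label-audit agreement; no multiple-testing adjustment is applied anywhere.

## The synthetic cohort generator

Each synthetic user receives one missed-OC query at a uniform time in the
window, with text synthesised from templates that contain exactly the
trigger vocabulary of the intended class — the classifier recovers intents
and attributes exactly, by design. Classifier robustness to spelling
variation, multilinguality or non-protagonist queries is out of scope, so
passing recovery tests says nothing about classification precision on real
logs; it validates the statistics downstream of classification.

Defaults with an empirical counterpart (all configurable):

* dose-count mention pmf (unspecified/1/2/3/4+) = 0.671/0.214/0.063/0.034/0.018;
* pill-type mention shares none/combined/progestin = 0.608/0.209/0.217
  (the excess over 1 is the both-mentions overlap, 3.4%);
* placebo mentions: 10% of users, drawn from those with no pill-type
  mention so the placebo stratum is not confounded with pill type;
* stratum pregnancy probabilities: minipill 0.087, placebo 0.002, ≥2 doses
  0.051 (precedence placebo > minipill > two-plus), applied per user with a
  normalised 2.1× multiplier for ages 30–34;
* the baseline probability (no special stratum) is **solved**, not set, so
  that the expected rate over the whole non-placebo cohort equals 0.047 —
  the headline figure. The published per-stratum figures (4.7% overall,
  4.7% non-minipill, 4.7% unspecified-dose, 4.5% placebo-complement) are
  mutually inconsistent with a 21.7% minipill share at 8.7%, so the
  cohort-level figure is taken as the anchor; the solved baseline is
  ≈ 0.032;
* follow-up probabilities per class (EC 0.08, abortion 0.06, miscarriage
  0.03 — free parameters chosen to give ≥ 500 users per stratum at
  n = 50,000) with normalised age-band multipliers 1.7/1.5 (under 30) and
  5.4 (30–34 for miscarriage);
* gap times: a two-part mixture — the configured within-24 h fraction as a
  uniform mass on [0, 1) day plus a log-normal tail (σ = 0.6) whose median
  is solved so the mixture median equals the configured value (EC 11 d
  / 0.37, abortion 28 d / 0.20, miscarriage 35 d / 0.07). A single
  log-normal matching both constraints would need σ ≈ 7, putting ~31% of
  its mass beyond one year and destroying the observable median; σ = 0.6
  keeps > 99% of the tail inside a one-year window so the configured median
  remains identifiable from the censored log;
* ages: a two-component normal mixture (35% at N(20, 4²), 65% at
  N(38.5, 9.7²), truncated to 13–80) giving mean ≈ 32, SD ≈ 12, mode 20;
  ages are reported for 80% of users; dose counts are weakly rank-coupled
  to age (20% copula mixing, giving Spearman ρ ≈ 0.07);
* conception offset: truncated normal (mean 14.4, SD 7.2) on [0, 28) days
  after the LMP; 19% of pregnancies are timed to the index cycle.

### Pregnancy-week query process and censoring

A pregnant user draws one gestational week k from a triangular pmf on weeks
4–20 peaking at week 8 and issues 1–3 queries (pmf 0.30/0.35/0.35), all
reporting week k, at dates `LMP + 7k + J` with independent integer jitter
J ~ U{−6..6} per query — re-queries within days of each other, as an
anxious searcher would. Queries after the window end are silently dropped:
that is the censoring mechanism the weights must undo. The jitter half-width
was calibrated by brute force (sweep over 4..8 at n = 40,000) so the cohort
median of per-user median pairwise LMP differences equals 4 days; 6 is the
calibrated value. With jitter 0 the dating rule is exactly inverted by the
gestation module — a structural test.

Timed pregnancies place the LMP at `index − conception offset`. Untimed
pregnancies must still emit their queries after the index date (otherwise
they would not count as follow-ups), which forces an asymmetry: a
later-cycle placement (LMP = index + U[7, 35] days; the 7-day floor keeps
the timed classifier exact under ±6 d jitter) makes the index date an
early proxy for the LMP and biases the weighted estimator low. The
generator therefore also places a share of untimed pregnancies in an
*earlier* cycle (LMP = index − U[35, 63] days: the user was already
pregnant when she missed the pill; the 35-day floor again protects the
timed classifier). That share is solved numerically — expected weight and
expected true observability are computed on a daily grid from the
configured week pmf, query-count pmf and jitter — so that, pooled over all
pregnant users, the index date is a calendar-unbiased stand-in for the LMP.
This encodes the identifying assumption of the weighting method rather than
tuning to any output: with it, 200 replicate simulations at n = 5,000 put
the mean weighted rate within Monte-Carlo noise of the configured truth
while the unweighted rate is ~20% low.

## Numerical conventions

Gap medians use the lower central order statistic on even counts; dates are
compared at day resolution except gap times (fractional days); conception
days are rounded with `numpy.rint`; the weight floor ε = 0.01 applies only
when weights enter a denominator; probability vectors must sum to 1 within
1e-9; empty classes yield explicit empty results (NaN medians), and an
all-tied correlation input yields an absent result rather than an error.

## Problem sizes and validation

The reference scenario uses n = 50,000 users (one simulate+analyze pass
takes a few seconds on one CPU), which yields roughly 1,700 observed
pregnancy reporters, ~340 timed pregnancies and ~4,800 users aged 30–34 —
enough for every stratum estimate to have a usable Monte-Carlo standard
error. Recovery tests assert agreement with the configured truths within
3 MC standard errors (10% for the EC gap median, ±1 day for the
LMP-consistency median); the estimator-calibration property uses 200
replicates at n = 5,000. With a 10% placebo share the placebo stratum
expects only ~9 observed pregnancies, so its recovered rate (truth 0.2%)
fluctuates by ±0.07 percentage points SE across seeds — an irreducible
property of a rare outcome at this cohort size.

## Known limitations

* Query text realism is deliberately minimal; classification
  precision/recall on real logs is untestable here.
* Users have a single missed-OC episode; repeat episodes are not
  re-anchored (mirroring the single-index design of the analysis).
* The weighting corrects observability only through the index-date/window
  geometry; it cannot correct users who never query about a pregnancy they
  carry, and the weighted estimator has no variance theory beyond the
  provided percentile bootstrap.
* The empirical week distribution is itself estimated from censored
  queries, which tilts it slightly toward early weeks; the effect on the
  weighted rate is well under one Monte-Carlo standard error at the
  reference size.
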