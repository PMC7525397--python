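"""Synthetic per-user query-log generator with a ground-truth sidecar.

The generator emulates the statistical structure the downstream analysis
assumes: each synthetic user issues one missed-oral-contraceptive query at a
uniformly random date inside a one-calendar-year window; a subset later issue
emergency-contraception, abortion or miscarriage queries at configurable
gap-time distributions; and a subset become pregnant and issue
pregnancy-week queries dated from a true last menstrual period (LMP).
Pregnancy-week queries falling after the window end are never emitted — this
right-censoring is exactly the phenomenon the observability weights in
:mod:`ocquery.censoring` are designed to undo.

Every parameter with an empirically reported counterpart defaults to that
reported value (dose-count distribution, pill-type mention shares, stratum
pregnancy rates, gap-time medians and within-24h fractions, conception-day
distribution, timed fraction, age moments, age-band multipliers).  Query
texts are synthesised from unambiguous templates so the rule-based
classifier recovers the intended label and attributes exactly; classifier
robustness to messy language is deliberately out of scope.

Two internal calibrations are solved from the configuration rather than set
by hand (see docs/methods.md):

* the per-user baseline pregnancy probability is solved so the expected
  rate over the non-placebo cohort equals ``preg_rate_nonplacebo``;
* untimed pregnancies are placed in a later cycle (LMP after the index
  query) or an earlier one, with the earlier-cycle share solved so the
  index date is a calendar-unbiased stand-in for the LMP — the identifying
  assumption of the censoring weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm as _norm
from scipy.stats import rankdata, truncnorm

SECONDS_PER_DAY = 86400

DOSE_LABELS = ["unspecified", "1", "2", "3", "4plus"]
PILL_CATS = ["none", "combined_only", "progestin_only", "both"]
FOLLOWUP_CLASSES = ["emergency_contraception", "abortion", "miscarriage"]


class ScenarioError(ValueError):
    """Invalid scenario configuration; message lists offending fields."""


@dataclass
class ScenarioConfig:
    """Generator parameters; defaults encode the reference cohort.

    Probabilities are per-user; gap-time parameters are (median days,
    fraction within 24 h); the conception offset is a truncated normal on
    [0, cycle_length) days after the LMP.
    """

    n_users: int = 50_000
    window_start: str = "2018-01-01"
    window_end: str = "2018-12-31"
    # optionally restrict index (first missed-OC query) dates to a sub-window,
    # e.g. January only for an uncensored scenario
    index_window: Optional[tuple] = None
    seed: int = 42

    # demographics: two-component normal mixture, mean ~32, SD ~12, mode 20
    age_mix_weight_young: float = 0.35
    age_young_mean: float = 20.0
    age_young_sd: float = 4.0
    age_older_mean: float = 38.5
    age_older_sd: float = 9.7
    age_min: int = 13
    age_max: int = 80
    age_known_prob: float = 0.80

    # missed-dose attributes
    dose_count_pmf: dict = field(
        default_factory=lambda: {
            "unspecified": 0.671, "1": 0.214, "2": 0.063, "3": 0.034, "4plus": 0.018,
        }
    )
    pill_mention_probs: dict = field(
        default_factory=lambda: {"none": 0.608, "combined": 0.209, "progestin_only": 0.217}
    )
    placebo_fraction: float = 0.10
    # copula-style mixing giving a weak positive age/dose-count association
    age_dose_link: float = 0.20

    # pregnancy model: cohort-level non-placebo target plus stratum rates
    preg_rate_nonplacebo: float = 0.047
    preg_rate_minipill: float = 0.087
    preg_rate_placebo: float = 0.002
    preg_rate_two_plus: float = 0.051
    timed_fraction: float = 0.19
    conception_mean: float = 14.4
    conception_sd: float = 7.2
    cycle_length: int = 28
    untimed_next_gap: tuple = (7, 35)    # LMP this many days AFTER index
    untimed_prior_gap: tuple = (35, 63)  # LMP this many days BEFORE index

    # follow-up query model
    followup_probs: dict = field(
        default_factory=lambda: {
            "emergency_contraception": 0.08, "abortion": 0.06, "miscarriage": 0.03,
        }
    )
    gap_params: dict = field(
        default_factory=lambda: {
            "emergency_contraception": (11.0, 0.37),
            "abortion": (28.0, 0.20),
            "miscarriage": (35.0, 0.07),
        }
    )
    gap_sigma: float = 0.6
    age_band_multipliers: dict = field(
        default_factory=lambda: {
            "abortion": ("under_30", 1.5),
            "emergency_contraception": ("under_30", 1.7),
            "pregnancy_week": ("30_to_34", 2.1),
            "miscarriage": ("30_to_34", 5.4),
        }
    )

    # pregnancy-week query process
    week_support: tuple = (4, 20)
    week_peak: int = 8
    n_week_queries_pmf: dict = field(default_factory=lambda: {1: 0.30, 2: 0.35, 3: 0.35})
    lmp_jitter_halfwidth: int = 6

    noise_queries_mean: float = 1.5

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        bad: list[str] = []
        if self.n_users < 0:
            bad.append("n_users must be >= 0")
        if np.datetime64(self.window_start) >= np.datetime64(self.window_end):
            bad.append("window_start must precede window_end")
        if self.index_window is not None:
            lo, hi = (np.datetime64(d) for d in self.index_window)
            if not (np.datetime64(self.window_start) <= lo <= hi
                    <= np.datetime64(self.window_end)):
                bad.append("index_window must lie inside the observation window")
        for name in ("dose_count_pmf", "n_week_queries_pmf"):
            pmf = getattr(self, name)
            if abs(sum(pmf.values()) - 1.0) > 1e-9 or any(v < 0 for v in pmf.values()):
                bad.append(f"{name} must be a probability vector summing to 1")
        pm = self.pill_mention_probs
        overlap = sum(pm.values()) - 1.0
        if overlap < -1e-9 or any(not 0 <= v <= 1 for v in pm.values()):
            bad.append("pill_mention_probs must cover the cohort (sum >= 1, overlap = both)")
        if not 0 <= self.placebo_fraction <= pm.get("none", 0):
            bad.append("placebo_fraction must be in [0, P(no pill-type mention)]")
        for name in ("preg_rate_nonplacebo", "preg_rate_minipill", "preg_rate_placebo",
                     "preg_rate_two_plus", "timed_fraction", "age_known_prob",
                     "age_dose_link"):
            if not 0 <= getattr(self, name) <= 1:
                bad.append(f"{name} must be in [0, 1]")
        for cls, p in self.followup_probs.items():
            if not 0 <= p <= 1:
                bad.append(f"followup_probs[{cls}] must be in [0, 1]")
        for cls, (med, f24) in self.gap_params.items():
            if med <= 0:
                bad.append(f"gap_params[{cls}] median must be > 0")
            if not 0 <= f24 < 1:
                bad.append(f"gap_params[{cls}] within-24h fraction must be in [0, 1)")
        if self.week_support[0] < 1 or self.week_support[1] > 45 \
                or self.week_support[0] > self.week_peak > self.week_support[1] \
                or self.week_support[0] >= self.week_support[1]:
            bad.append("week_support must satisfy 1 <= lo <= peak <= hi <= 45")
        if self.lmp_jitter_halfwidth < 0:
            bad.append("lmp_jitter_halfwidth must be >= 0")
        if self.untimed_next_gap[0] <= self.lmp_jitter_halfwidth:
            bad.append("untimed_next_gap lower bound must exceed the jitter half-width")
        if self.untimed_prior_gap[0] < self.cycle_length + self.lmp_jitter_halfwidth:
            bad.append("untimed_prior_gap lower bound must be >= cycle_length + jitter")
        if self.base_rate() < 0:
            bad.append("stratum pregnancy rates inconsistent: implied baseline rate < 0")
        if bad:
            raise ScenarioError("; ".join(bad))

    # ------------------------------------------------------------------ #
    @property
    def n_days(self) -> int:
        return int(
            (np.datetime64(self.window_end) - np.datetime64(self.window_start)).astype(int)
        ) + 1

    def pill_category_probs(self) -> np.ndarray:
        """P(none, combined-only, progestin-only, both); overlap = sum - 1."""
        pm = self.pill_mention_probs
        both = max(0.0, pm["combined"] + pm["progestin_only"] + pm["none"] - 1.0)
        return np.array(
            [pm["none"], pm["combined"] - both, pm["progestin_only"] - both, both]
        )

    def stratum_shares(self) -> dict[str, float]:
        """Cohort shares of the pregnancy-rate strata (precedence order)."""
        p_prog = self.pill_mention_probs["progestin_only"]
        p_plac = self.placebo_fraction
        d2 = sum(self.dose_count_pmf[k] for k in ("2", "3", "4plus"))
        rest = 1.0 - p_prog - p_plac
        return {
            "placebo": p_plac,
            "minipill": p_prog,
            "two_plus": rest * d2,
            "baseline": rest * (1.0 - d2),
        }

    def base_rate(self) -> float:
        """Baseline per-user pregnancy probability.

        Solved so that the expected rate over the non-placebo cohort equals
        ``preg_rate_nonplacebo``.
        """
        s = self.stratum_shares()
        target = self.preg_rate_nonplacebo * (1.0 - s["placebo"])
        return (
            target
            - s["minipill"] * self.preg_rate_minipill
            - s["two_plus"] * self.preg_rate_two_plus
        ) / s["baseline"]

    def week_pmf(self) -> tuple[np.ndarray, np.ndarray]:
        """Triangular gestational-week query distribution."""
        lo, hi = self.week_support
        peak = self.week_peak
        weeks = np.arange(lo, hi + 1)
        w = np.where(
            weeks <= peak,
            weeks - lo + 1.0,
            (peak - lo + 1.0) * (hi + 1.0 - weeks) / (hi + 1.0 - peak),
        )
        return weeks, w / w.sum()

    def conception_pmf(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer-day pmf of the truncated-normal conception offset."""
        edges = np.arange(self.cycle_length + 1) - 0.5
        a = (0.0 - self.conception_mean) / self.conception_sd
        b = (self.cycle_length - self.conception_mean) / self.conception_sd
        cdf = truncnorm.cdf(
            np.clip(edges, 0, self.cycle_length), a, b,
            loc=self.conception_mean, scale=self.conception_sd,
        )
        pmf = np.diff(cdf)
        return np.arange(self.cycle_length), pmf / pmf.sum()

    def conception_offset_mean(self) -> float:
        a = (0.0 - self.conception_mean) / self.conception_sd
        b = (self.cycle_length - self.conception_mean) / self.conception_sd
        return float(
            truncnorm.mean(a, b, loc=self.conception_mean, scale=self.conception_sd)
        )

    def _min_jitter_cdf(self, x: np.ndarray) -> np.ndarray:
        """P(min of the per-user jitters <= x), averaged over the query-count pmf."""
        h = self.lmp_jitter_halfwidth
        if h == 0:
            cdf_j = (x >= 0).astype(float)
        else:
            cdf_j = np.clip((np.floor(x) + h + 1) / (2 * h + 1), 0.0, 1.0)
        out = np.zeros_like(cdf_j, dtype=float)
        for m, pm in self.n_week_queries_pmf.items():
            out += pm * (1.0 - (1.0 - cdf_j) ** m)
        return out

    def untimed_prior_share(self) -> float:
        """Share of untimed pregnancies placed in an earlier cycle.

        Solved so that, pooled over all pregnant users, the expected
        index-date observability weight equals the expected true probability
        of emitting at least one pregnancy-week query inside the window.
        """
        D = self.n_days
        end = D - 1
        weeks, p = self.week_pmf()
        t = np.arange(D)

        # expected weight, using the censoring-tilted estimate of p(k)
        p_hat = p * np.clip(D - 7.0 * weeks, 0.0, None)
        p_hat = p_hat / p_hat.sum()
        w_t = ((t[:, None] + 7 * weeks[None, :]) <= end) @ p_hat
        e_weight = w_t.mean()

        h = self.lmp_jitter_halfwidth

        def e_obs(lmp_offsets: np.ndarray, offset_pmf: np.ndarray,
                  conditioned: bool) -> float:
            """E[P(>=1 emitted week query)] for LMP = index + offset."""
            total = 0.0
            for off, po in zip(lmp_offsets, offset_pmf):
                if conditioned and off < 0:
                    k_min = math.ceil((-off + h) / 7.0)
                    mask = weeks >= max(weeks[0], k_min)
                else:
                    mask = np.ones_like(weeks, dtype=bool)
                pk = p[mask] / p[mask].sum()
                slack = end - (t[:, None] + off) - 7 * weeks[None, mask]
                total += po * float((self._min_jitter_cdf(slack) @ pk).mean())
            return total

        off_days, off_pmf = self.conception_pmf()
        e_timed = e_obs(-off_days, off_pmf, conditioned=True)
        lo, hi = self.untimed_next_gap
        u = np.arange(lo, hi + 1)
        e_next = e_obs(u, np.full(len(u), 1.0 / len(u)), conditioned=False)
        lo, hi = self.untimed_prior_gap
        v = np.arange(lo, hi + 1)
        e_prior = e_obs(-v, np.full(len(v), 1.0 / len(v)), conditioned=True)

        tf = self.timed_fraction
        denom = (1.0 - tf) * (e_prior - e_next)
        if denom == 0:
            return 0.5
        s = (e_weight - tf * e_timed - (1.0 - tf) * e_next) / denom
        return float(np.clip(s, 0.0, 1.0))

    # ------------------------------------------------------------------ #
    def expected(self) -> dict[str, float]:
        """Configured truths that the pipeline is expected to recover."""
        shares = self.stratum_shares()
        rates = {
            "placebo": self.preg_rate_placebo,
            "minipill": self.preg_rate_minipill,
            "two_plus": self.preg_rate_two_plus,
            "baseline": self.base_rate(),
        }
        # users mentioning >= 2 doses span all strata; dose count is
        # independent of pill type and placebo status
        p_prog = self.pill_mention_probs["progestin_only"]
        p_plac = self.placebo_fraction
        two_plus_rate = (
            p_prog * rates["minipill"]
            + p_plac * rates["placebo"]
            + (1 - p_prog - p_plac) * rates["two_plus"]
        )
        ec_med, ec_f24 = self.gap_params["emergency_contraception"]
        return {
            "nonplacebo_rate": self.preg_rate_nonplacebo,
            "minipill_rate": self.preg_rate_minipill,
            "placebo_rate": self.preg_rate_placebo,
            "two_plus_rate": two_plus_rate,
            "baseline_rate": rates["baseline"],
            "ec_median_gap_days": ec_med,
            "ec_fraction_within_24h": ec_f24,
            "conception_day_mean": self.conception_offset_mean(),
            "lmp_consistency_days": 4.0,
            "timed_fraction": self.timed_fraction,
            "miscarriage_age_ratio": self.age_band_multipliers["miscarriage"][1],
        }

    # ------------------------------------------------------------------ #
    @classmethod
    def from_yaml(cls, path: str) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ScenarioError(f"unknown config keys: {sorted(unknown)}")
        for key in ("untimed_next_gap", "untimed_prior_gap", "week_support", "index_window"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        for key in ("n_week_queries_pmf",):
            if key in data:
                data[key] = {int(k): v for k, v in data[key].items()}
        if "gap_params" in data:
            data["gap_params"] = {k: tuple(v) for k, v in data["gap_params"].items()}
        if "age_band_multipliers" in data:
            data["age_band_multipliers"] = {
                k: (v[0], float(v[1])) for k, v in data["age_band_multipliers"].items()
            }
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        data = asdict(self)
        for key in ("untimed_next_gap", "untimed_prior_gap", "week_support"):
            data[key] = list(data[key])
        if data["index_window"] is not None:
            data["index_window"] = list(data["index_window"])
        data["gap_params"] = {k: list(v) for k, v in data["gap_params"].items()}
        data["age_band_multipliers"] = {
            k: [v[0], v[1]] for k, v in data["age_band_multipliers"].items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------- #
# query-text templates: every template contains exactly the trigger
# vocabulary of its intended class and nothing that could fire another rule

_MISS_VERBS = ["missed", "forgot", "skipped"]
_TAILS = ["", " what should i do", " am i protected", " help",
          " this morning", " yesterday", " can i get pregnant now"]
_GENERIC_OC = ["birth control", "my birth control", "my contraceptive pill"]
_PROGESTIN_GENERIC = ["minipill", "my minipill"]

_PREG_TEMPLATES = [
    "pregnancy week {w} symptoms",
    "what to expect on week {w} of pregnancy",
    "{w} weeks pregnant what to expect",
    "week {w} of pregnancy cramps",
    "{w} weeks pregnant ultrasound",
    "pregnancy symptoms at week {w}",
    "baby size at {w} weeks of pregnancy",
    "week {w} pregnancy checklist",
]

_EC_TEMPLATES = [
    "plan b price near me",
    "where can i buy plan b",
    "how effective is plan b",
    "plan b side effects",
    "morning after pill side effects",
    "how long do i have to take the morning after pill",
    "does the morning after pill always work",
    "plan b coupon walgreens",
]

_MISC_TEMPLATES = [
    "bleeding after miscarriage",
    "how long does cramping last after miscarriage",
    "when can we try again post miscarriage",
    "i had a miscarriage what happens next",
    "period after miscarriage",
    "recovery time post miscarriage",
    "i had a miscarriage and feel awful",
    "spotting after miscarriage normal",
]

_ABORT_TEMPLATES = [
    "abortion clinic near me",
    "how much does an abortion cost",
    "abortion pill how does it work",
    "what happens during an abortion",
    "how late can you get an abortion",
    "abortion recovery time",
    "where to get an abortion",
    "does insurance cover abortion",
]

_NOISE_TEMPLATES = [
    "weather tomorrow",
    "cheap flights to denver",
    "chicken soup recipe",
    "movie times near me",
    "how to tie a tie",
    "best phone deals",
    "football scores today",
    "dry skin remedies",
    "bus schedule downtown",
    "translate hello to spanish",
    "missed flight compensation",
    "skipped breakfast effects",
    "forgot my email password",
    "abortion law debate 2018",
    "abortion ban news today",
    "plan b movie review",
    "morning after pill legislation vote",
    "celebrity pregnancy news",
]

_NUMBER_WORDS = ["one", "two", "three", "four", "five", "six", "seven", "eight", "nine"]


def _render_missed(rng: np.random.Generator, pill_cat: str, n_doses: int,
                   placebo: bool, combined_brands: list[str],
                   progestin_brands: list[str]) -> str:
    verb = _MISS_VERBS[rng.integers(len(_MISS_VERBS))]
    if pill_cat == "none":
        oc = _GENERIC_OC[rng.integers(len(_GENERIC_OC))]
    elif pill_cat == "combined_only":
        oc = combined_brands[rng.integers(len(combined_brands))]
    elif pill_cat == "progestin_only":
        pool = progestin_brands + _PROGESTIN_GENERIC
        oc = pool[rng.integers(len(pool))]
    else:  # both
        oc = (combined_brands[rng.integers(len(combined_brands))]
              + " and " + progestin_brands[rng.integers(len(progestin_brands))])
    tail = _TAILS[rng.integers(len(_TAILS))]
    if placebo:
        if n_doses > 0:
            count = str(n_doses)
            return f"{verb} {count} placebo pills of my {oc}{tail}"
        return f"{verb} a placebo pill of my {oc}{tail}"
    if n_doses > 0:
        count = (_NUMBER_WORDS[n_doses - 1]
                 if n_doses <= 9 and rng.random() < 0.3 else str(n_doses))
        if rng.random() < 0.5:
            return f"{verb} {count} {oc} pills{tail}"
        return f"{verb} {count} doses of {oc}{tail}"
    if rng.random() < 0.5:
        return f"{verb} my {oc} pill{tail}"
    return f"i {verb} a dose of {oc}{tail}"


def _solve_gap_lognormal(median: float, f24: float, sigma: float) -> float:
    """mu of the log-normal tail so the 24h-spike mixture has the target median."""
    q = (0.5 - f24) / (1.0 - f24)
    return math.log(median) - sigma * _norm.ppf(q)


def _draw_conditional_weeks(rng: np.random.Generator, weeks: np.ndarray,
                            pmf: np.ndarray, k_min: np.ndarray) -> np.ndarray:
    """One gestational week per user from pmf restricted to >= k_min[i]."""
    out = np.empty(len(k_min), dtype=int)
    for km in np.unique(k_min):
        idx = np.where(k_min == km)[0]
        mask = weeks >= km
        p = pmf[mask] / pmf[mask].sum()
        out[idx] = rng.choice(weeks[mask], size=len(idx), p=p)
    return out


def generate_cohort(
    config: ScenarioConfig,
    lexicon=None,
    include_intent: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (query log, ground truth) for one scenario.

    The log has columns user_id, timestamp, text, age, gender (plus
    ``intent`` when ``include_intent``); the truth sidecar has one row per
    user with the latent state needed for parameter-recovery tests.
    """
    from .lexicon import Lexicon

    config.validate()
    if lexicon is None:
        lexicon = Lexicon.default()
    rng = np.random.default_rng(config.seed)
    n = config.n_users
    D = config.n_days
    end_day = D - 1
    start = np.datetime64(config.window_start, "s")

    user_id = np.array([f"u{i:07d}" for i in range(n)])
    if config.index_window is not None:
        lo = int((np.datetime64(config.index_window[0]) - np.datetime64(config.window_start)).astype(int))
        hi = int((np.datetime64(config.index_window[1]) - np.datetime64(config.window_start)).astype(int))
        sec_lo, sec_hi = lo * SECONDS_PER_DAY, (hi + 1) * SECONDS_PER_DAY
    else:
        sec_lo, sec_hi = 0, D * SECONDS_PER_DAY
    index_sec = rng.integers(sec_lo, sec_hi, size=n) if n else np.array([], dtype=int)
    index_day = index_sec // SECONDS_PER_DAY

    # demographics
    young = rng.random(n) < config.age_mix_weight_young
    age = np.where(
        young,
        rng.normal(config.age_young_mean, config.age_young_sd, n),
        rng.normal(config.age_older_mean, config.age_older_sd, n),
    )
    age = np.clip(np.rint(age), config.age_min, config.age_max).astype(int)
    age_known = rng.random(n) < config.age_known_prob

    # pill-type mention category
    pill_cat = rng.choice(PILL_CATS, size=n, p=config.pill_category_probs())
    pill_combined = np.isin(pill_cat, ["combined_only", "both"])
    pill_progestin = np.isin(pill_cat, ["progestin_only", "both"])

    # dose-count category, weakly rank-coupled to age
    pmf = np.array([config.dose_count_pmf[k] for k in DOSE_LABELS])
    cum = np.cumsum(pmf)
    if n:
        age_rank = (rankdata(age + rng.normal(0, 1e-6, n)) - 0.5) / n
    else:
        age_rank = np.array([])
    q = np.where(rng.random(n) < config.age_dose_link, age_rank, rng.random(n))
    dose_idx = np.minimum(np.searchsorted(cum, q, side="right"), len(DOSE_LABELS) - 1)
    dose_cat = np.array(DOSE_LABELS, dtype=object)[dose_idx] if n else np.array([], dtype=object)
    n_doses = np.select(
        [dose_idx == 1, dose_idx == 2, dose_idx == 3, dose_idx == 4],
        [1, 2, 3, 0], default=0,
    )
    n_doses = np.where(dose_idx == 4, rng.integers(4, 7, size=n), n_doses)

    # placebo mentions come from users with no pill-type mention
    p_none = config.pill_mention_probs["none"]
    placebo = (pill_cat == "none") & (rng.random(n) < config.placebo_fraction / p_none)

    # pregnancy-rate stratum (precedence: placebo > minipill > two_plus)
    stratum = np.select(
        [placebo, pill_progestin, dose_idx >= 2],
        ["placebo", "minipill", "two_plus"], default="baseline",
    ) if n else np.array([], dtype=object)
    rate = np.select(
        [stratum == "placebo", stratum == "minipill", stratum == "two_plus"],
        [config.preg_rate_placebo, config.preg_rate_minipill, config.preg_rate_two_plus],
        default=config.base_rate(),
    ) if n else np.array([])

    def band_mask(band: str) -> np.ndarray:
        if band == "under_30":
            return age < 30
        if band == "30_to_34":
            return (age >= 30) & (age <= 34)
        raise ScenarioError(f"unknown age band {band!r}")

    def age_multiplier(cls: str) -> np.ndarray:
        if not n:
            return np.array([])
        band, mult = config.age_band_multipliers.get(cls, ("under_30", 1.0))
        m = np.where(band_mask(band), mult, 1.0)
        return m / m.mean()

    preg_prob = np.clip(rate * age_multiplier("pregnancy_week"), 0.0, 1.0)
    pregnant = rng.random(n) < preg_prob

    # pregnancy timing: LMP relative to the index day
    conception_offset = np.rint(
        truncnorm.rvs(
            (0 - config.conception_mean) / config.conception_sd,
            (config.cycle_length - config.conception_mean) / config.conception_sd,
            loc=config.conception_mean, scale=config.conception_sd,
            size=n, random_state=rng,
        )
    ).astype(int) if n else np.array([], dtype=int)
    conception_offset = np.clip(conception_offset, 0, config.cycle_length - 1)
    timed = pregnant & (rng.random(n) < config.timed_fraction)
    prior_share = config.untimed_prior_share()
    prior_cycle = rng.random(n) < prior_share
    lo_n, hi_n = config.untimed_next_gap
    lo_p, hi_p = config.untimed_prior_gap
    next_gap = rng.integers(lo_n, hi_n + 1, size=n) if n else np.array([], dtype=int)
    prior_gap = rng.integers(lo_p, hi_p + 1, size=n) if n else np.array([], dtype=int)
    lmp_day = np.where(
        timed, index_day - conception_offset,
        np.where(prior_cycle, index_day - prior_gap, index_day + next_gap),
    )
    lmp_day = np.where(pregnant, lmp_day, 0)

    # pregnancy-week queries: one gestational week per user, re-queried with
    # independent day-level dating jitter
    weeks_supp, week_p = config.week_pmf()
    m_vals = np.array(sorted(config.n_week_queries_pmf))
    m_pmf = np.array([config.n_week_queries_pmf[int(v)] for v in m_vals])
    h = config.lmp_jitter_halfwidth

    preg_idx = np.where(pregnant)[0]
    n_preg = len(preg_idx)
    m_counts = rng.choice(m_vals, size=n_preg, p=m_pmf) if n_preg else np.array([], dtype=int)
    delta = index_day[preg_idx] - lmp_day[preg_idx]  # >0 when LMP precedes index
    k_min = np.maximum(weeks_supp[0], np.ceil((np.maximum(delta, 0) + h) / 7.0).astype(int))
    k_user = (_draw_conditional_weeks(rng, weeks_supp, week_p, k_min)
              if n_preg else np.array([], dtype=int))

    pq_user = np.repeat(preg_idx, m_counts)
    pq_week = np.repeat(k_user, m_counts)
    pq_lmp = np.repeat(lmp_day[preg_idx], m_counts)
    jitter = rng.integers(-h, h + 1, size=len(pq_user)) if h else np.zeros(len(pq_user), int)
    pq_day = pq_lmp + 7 * pq_week + jitter
    pq_sec = pq_day * SECONDS_PER_DAY + rng.integers(0, SECONDS_PER_DAY, size=len(pq_user))
    pq_emit = pq_day <= end_day
    # by construction queries never precede the index query
    assert not len(pq_day) or (pq_day >= index_day[pq_user]).all()

    n_week_emitted = np.zeros(n, dtype=int)
    if len(pq_user):
        np.add.at(n_week_emitted, pq_user[pq_emit], 1)
    n_week_intended = np.zeros(n, dtype=int)
    n_week_intended[preg_idx] = m_counts

    # follow-up queries (first occurrence per class per user)
    follow_rows = {}
    truth_follow = {}
    for cls in FOLLOWUP_CLASSES:
        p_cls = np.clip(
            config.followup_probs[cls] * age_multiplier(cls), 0.0, 1.0
        )
        has = rng.random(n) < p_cls
        idx = np.where(has)[0]
        med, f24 = config.gap_params[cls]
        mu = _solve_gap_lognormal(med, f24, config.gap_sigma)
        spike = rng.random(len(idx)) < f24
        gap_days = np.where(
            spike,
            rng.random(len(idx)),
            rng.lognormal(mu, config.gap_sigma, size=len(idx)),
        )
        sec = index_sec[idx] + np.rint(gap_days * SECONDS_PER_DAY).astype(np.int64)
        emit = sec <= D * SECONDS_PER_DAY - 1
        follow_rows[cls] = (idx[emit], sec[emit])
        gaps = np.full(n, np.nan)
        gaps[idx] = gap_days
        emitted = np.zeros(n, dtype=bool)
        emitted[idx[emit]] = True
        truth_follow[cls] = (has, gaps, emitted)

    # unrelated background queries
    noise_counts = rng.poisson(config.noise_queries_mean, size=n) if n else np.array([], dtype=int)
    noise_user = np.repeat(np.arange(n), noise_counts)
    noise_sec = rng.integers(0, D * SECONDS_PER_DAY, size=len(noise_user))

    # ---------------- assemble query rows ---------------- #
    rows_user: list[np.ndarray] = [np.arange(n)]
    rows_sec: list[np.ndarray] = [index_sec]
    rows_intent: list[np.ndarray] = [np.full(n, "missed_oc", dtype=object)]
    missed_texts = [
        _render_missed(rng, pill_cat[i], int(n_doses[i]), bool(placebo[i]),
                       lexicon.combined_brands, lexicon.progestin_brands)
        for i in range(n)
    ]
    rows_text: list[list[str]] = [missed_texts]

    emit_idx = np.where(pq_emit)[0]
    tpl = rng.integers(0, len(_PREG_TEMPLATES), size=len(emit_idx))
    rows_user.append(pq_user[emit_idx])
    rows_sec.append(pq_sec[emit_idx])
    rows_intent.append(np.full(len(emit_idx), "pregnancy_week", dtype=object))
    rows_text.append(
        [_PREG_TEMPLATES[t].format(w=int(pq_week[i])) for t, i in zip(tpl, emit_idx)]
    )

    for cls, templates in (
        ("emergency_contraception", _EC_TEMPLATES),
        ("abortion", _ABORT_TEMPLATES),
        ("miscarriage", _MISC_TEMPLATES),
    ):
        idx, sec = follow_rows[cls]
        tpl = rng.integers(0, len(templates), size=len(idx))
        rows_user.append(idx)
        rows_sec.append(sec)
        rows_intent.append(np.full(len(idx), cls, dtype=object))
        rows_text.append([templates[t] for t in tpl])

    tpl = rng.integers(0, len(_NOISE_TEMPLATES), size=len(noise_user))
    rows_user.append(noise_user)
    rows_sec.append(noise_sec)
    rows_intent.append(np.full(len(noise_user), "other", dtype=object))
    rows_text.append([_NOISE_TEMPLATES[t] for t in tpl])

    all_user = np.concatenate(rows_user) if rows_user else np.array([], dtype=int)
    all_sec = np.concatenate(rows_sec).astype(np.int64)
    all_intent = np.concatenate(rows_intent) if rows_intent else np.array([], dtype=object)
    all_text = [t for chunk in rows_text for t in chunk]

    log = pd.DataFrame(
        {
            "user_id": user_id[all_user] if n else np.array([], dtype=object),
            "timestamp": start + all_sec.astype("timedelta64[s]"),
            "text": all_text,
            "age": pd.array(
                np.where(age_known[all_user], age[all_user], -1), dtype="Int64"
            ) if n else pd.array([], dtype="Int64"),
            "gender": "female",
        }
    )
    if n:
        log.loc[log["age"] == -1, "age"] = pd.NA
    if include_intent:
        log["intent"] = all_intent
    log = log.sort_values("timestamp", kind="stable").reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "user_id": user_id,
            "index_ts": start + index_sec.astype("timedelta64[s]") if n else
            np.array([], dtype="datetime64[s]"),
            "age": age,
            "age_known": age_known,
            "pill_cat": pill_cat,
            "placebo": placebo,
            "dose_cat": dose_cat,
            "n_doses": n_doses,
            "stratum": stratum,
            "preg_prob": preg_prob if n else np.array([]),
            "pregnant": pregnant,
            "timed": timed,
            "lmp_day": np.where(
                pregnant,
                (np.datetime64(config.window_start) + lmp_day).astype(str),
                "",
            ) if n else np.array([], dtype=object),
            "conception_offset": np.where(pregnant, conception_offset, -1),
            "n_week_queries": n_week_intended,
            "n_week_queries_emitted": n_week_emitted,
            "censored": pregnant & (n_week_emitted == 0),
        }
    )
    for cls in FOLLOWUP_CLASSES:
        has, gaps, emitted = truth_follow[cls]
        truth[f"{cls}_intended"] = has
        truth[f"{cls}_gap_days"] = gaps
        truth[f"{cls}_emitted"] = emitted
    return log, truth


# ---------------------------------------------------------------------- #
def write_log(log: pd.DataFrame, path: str) -> None:
    out = log.drop(columns=[c for c in ("intent",) if c in log.columns])
    out.to_csv(path, sep="\t", index=False, date_format="%Y-%m-%dT%H:%M:%S")


def write_truth(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False, date_format="%Y-%m-%dT%H:%M:%S")


def read_truth(path: str) -> pd.DataFrame:
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", pd.errors.ParserWarning)
            truth = pd.read_csv(
                path, sep="\t", dtype={"user_id": str, "lmp_day": str}, index_col=False
            )
        if len(truth):
            truth["index_ts"] = pd.to_datetime(truth["index_ts"]).astype("datetime64[s]")
            truth["lmp_day"] = truth["lmp_day"].fillna("")
    except (pd.errors.ParserError, pd.errors.ParserWarning, ValueError, KeyError) as exc:
        raise ValueError(f"malformed ground-truth file {path!r}: {exc}") from exc
    return truth
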