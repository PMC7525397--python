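"""Right-censoring observability weights and weighted pregnancy rates.

A pregnancy initiated late in the observation window produces most of its
pregnancy-week queries after the window closes, so late index dates make
pregnancies systematically unobservable.  The correction estimates the
empirical distribution p(k) of reported gestational weeks over the whole
log, then assigns each missed-OC user a weight

    w(t) = sum_k p(k) * 1[t + 7k <= window_end]

— the probability mass of week mentions still observable from their index
date t.  A January user gets weight 1 (the full term fits in the window); a
December user gets a small weight.  The weighted pregnancy rate divides the
count of observed pregnancy reporters by the sum of weights (an effective,
observable-equivalent cohort size); weights enter the denominator only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

DEFAULT_WEIGHT_FLOOR = 0.01


@dataclass
class WeekDistribution:
    """Empirical probability that a pregnancy query mentions week k."""

    weeks: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.weeks = np.asarray(self.weeks, dtype=int)
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.weeks) != len(self.probs):
            raise ValueError("weeks and probs must have equal length")
        if (self.probs < 0).any() or abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("probs must be non-negative and sum to 1")

    @classmethod
    def from_counts(cls, weeks: Iterable[int]) -> "WeekDistribution":
        values, counts = np.unique(np.asarray(list(weeks), dtype=int), return_counts=True)
        return cls(values, counts / counts.sum())

    def as_dict(self) -> dict[int, float]:
        return {int(k): float(p) for k, p in zip(self.weeks, self.probs)}


def estimate_week_distribution(classified: pd.DataFrame) -> WeekDistribution:
    """p(k) = share of pregnancy-week queries mentioning week k.

    Estimated from all pregnancy-week queries in the log (not only those of
    missed-OC users) to maximise the sample.
    """
    weeks = classified.loc[
        classified["label"] == "pregnancy_week", "pregnancy_week"
    ].dropna()
    if len(weeks) == 0:
        raise ValueError(
            "no pregnancy_week queries in the log; supply a configured prior "
            "week distribution instead"
        )
    return WeekDistribution.from_counts(weeks.astype(int))


def compute_weight(index_date, dist: WeekDistribution, window_end) -> float:
    """Observability weight for a single index date (not floored)."""
    index_day = np.datetime64(index_date, "D")
    end = np.datetime64(window_end, "D")
    observable = (index_day + 7 * dist.weeks.astype("timedelta64[D]")) <= end
    return float(dist.probs[observable].sum())


def compute_weights(index_dates: pd.Series, dist: WeekDistribution, window_end) -> pd.Series:
    """Vectorised weights for a Series of index timestamps."""
    days = index_dates.to_numpy().astype("datetime64[D]")
    end = np.datetime64(window_end, "D")
    mat = (days[:, None] + 7 * dist.weeks[None, :].astype("timedelta64[D]")) <= end
    return pd.Series(mat @ dist.probs, index=index_dates.index, name="weight")


def weighted_pregnancy_rate(
    weights: np.ndarray,
    pregnant: np.ndarray,
    floor: float = DEFAULT_WEIGHT_FLOOR,
    estimator: str = "denominator",
) -> dict[str, float]:
    """Censoring-corrected pregnancy rate.

    ``denominator`` (default): observed pregnancies divided by the sum of
    floored weights — a user observed pregnant counts 1 in the numerator
    regardless of weight.  ``horvitz_thompson`` additionally inverse-weights
    the numerator (sensitivity variant).
    """
    weights = np.clip(np.asarray(weights, dtype=float), floor, 1.0)
    pregnant = np.asarray(pregnant, dtype=bool)
    if len(weights) == 0:
        return {"weighted_rate": float("nan"), "unweighted_rate": float("nan"),
                "n_users": 0, "effective_n": 0.0, "n_pregnant": 0}
    if estimator == "denominator":
        rate = pregnant.sum() / weights.sum()
    elif estimator == "horvitz_thompson":
        rate = (pregnant / weights).sum() / len(weights)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return {
        "weighted_rate": float(rate),
        "unweighted_rate": float(pregnant.mean()),
        "n_users": int(len(weights)),
        "effective_n": float(weights.sum()),
        "n_pregnant": int(pregnant.sum()),
    }


GROUPINGS = ("pill_type", "placebo", "dose_count_2plus")


def subgroup_rates(
    cohort: pd.DataFrame,
    grouping: str,
    floor: float = DEFAULT_WEIGHT_FLOOR,
    min_stratum_size: int = 50,
) -> pd.DataFrame:
    """Weighted rates per stratum of a cohort table.

    ``cohort`` has one row per missed-OC user with columns ``weight``,
    ``pregnant`` and the attribute columns ``pill_combined``,
    ``pill_progestin``, ``placebo_mentioned``, ``n_missed_doses``.  For
    ``pill_type`` a user mentioning both kinds of brand is counted in both
    strata, so stratum sizes can exceed the cohort.
    """
    if grouping == "pill_type":
        strata = {
            "combined": cohort["pill_combined"].to_numpy(dtype=bool),
            "progestin_only": cohort["pill_progestin"].to_numpy(dtype=bool),
            "unspecified": ~(cohort["pill_combined"] | cohort["pill_progestin"]).to_numpy(dtype=bool),
        }
    elif grouping == "placebo":
        mask = cohort["placebo_mentioned"].to_numpy(dtype=bool)
        strata = {"placebo": mask, "non_placebo": ~mask}
    elif grouping == "dose_count_2plus":
        doses = cohort["n_missed_doses"].to_numpy(dtype=float)
        two_plus = np.nan_to_num(doses, nan=0.0) >= 2
        strata = {"two_plus": two_plus, "other": ~two_plus}
    else:
        raise ValueError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")

    rows = []
    for name, mask in strata.items():
        res = weighted_pregnancy_rate(
            cohort.loc[mask, "weight"].to_numpy(),
            cohort.loc[mask, "pregnant"].to_numpy(),
            floor=floor,
        )
        res = {"stratum": name, **res, "small_stratum": int(mask.sum()) < min_stratum_size}
        rows.append(res)
    return pd.DataFrame(rows)


def bootstrap_rate_ci(
    weights: np.ndarray,
    pregnant: np.ndarray,
    n_boot: int = 1000,
    alpha: float = 0.05,
    floor: float = DEFAULT_WEIGHT_FLOOR,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI (over users) for the weighted rate."""
    rng = np.random.default_rng(seed)
    weights = np.asarray(weights, dtype=float)
    pregnant = np.asarray(pregnant, dtype=bool)
    n = len(weights)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        stats[b] = weighted_pregnancy_rate(weights[idx], pregnant[idx], floor)["weighted_rate"]
    return tuple(np.quantile(stats, [alpha / 2, 1 - alpha / 2]))
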