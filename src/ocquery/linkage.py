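"""Per-user timeline linkage and follow-up gap-time statistics.

A user enters the cohort when they issue at least one missed-OC query; the
timestamp of the first such query is the *index date*.  Follow-up analysis
considers the first query of each class at or after the index date
(same-day follow-ups count, with gap 0 — the clinically salient case for
emergency contraception).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .query_model import FOLLOWUP_LABELS

logger = logging.getLogger(__name__)


@dataclass
class GapStats:
    """Gap-time summary for one follow-up class."""

    n_users: int
    median_gap_days: float  # NaN when the class is empty
    fraction_within_24h: float
    gaps: np.ndarray


@dataclass
class Timelines:
    """Linked per-user timelines in columnar form.

    ``index_dates``: Series indexed by user_id with the first missed_oc
    timestamp.  ``followups``: one row per follow-up query (at or after the
    index date) with its class label and gap in fractional days.
    ``n_users_dropped``: users in the log with no missed_oc query.
    """

    index_dates: pd.Series
    followups: pd.DataFrame
    n_users_dropped: int

    @property
    def n_users(self) -> int:
        return len(self.index_dates)

    def first_followups(self, label: str) -> pd.DataFrame:
        """First follow-up query of the given class per user."""
        sub = self.followups[self.followups["label"] == label]
        return sub.loc[sub.groupby("user_id")["timestamp"].idxmin()]


def build_timelines(classified: pd.DataFrame) -> Timelines:
    """Link classified queries into per-user timelines.

    Users without any missed_oc query are dropped (count logged).  Queries
    are ordered by timestamp with ties broken by stable input order.
    """
    ordered = classified.sort_values("timestamp", kind="stable")
    missed = ordered[ordered["label"] == "missed_oc"]
    index_dates = missed.groupby("user_id")["timestamp"].min()
    n_dropped = classified["user_id"].nunique() - len(index_dates)
    if n_dropped:
        logger.info("dropped %d users with no missed_oc query", n_dropped)

    follow = ordered[ordered["label"].isin(FOLLOWUP_LABELS)].copy()
    follow = follow[follow["user_id"].isin(index_dates.index)]
    if len(follow):
        idx = index_dates.reindex(follow["user_id"]).to_numpy()
        follow["gap_days"] = (
            follow["timestamp"].to_numpy() - idx
        ) / np.timedelta64(1, "D")
        follow = follow[follow["gap_days"] >= 0]
    else:
        follow["gap_days"] = pd.Series(dtype=float)
    keep = ["user_id", "timestamp", "label", "gap_days"]
    if "pregnancy_week" in follow.columns:
        keep.append("pregnancy_week")
    return Timelines(
        index_dates=index_dates,
        followups=follow[keep].reset_index(drop=True),
        n_users_dropped=int(n_dropped),
    )


def median_low(values: np.ndarray) -> float:
    """Median taking the lower of the two central order statistics."""
    values = np.sort(np.asarray(values, dtype=float))
    if len(values) == 0:
        return float("nan")
    return float(values[(len(values) - 1) // 2])


def gap_stats(timelines: Timelines, label: str) -> GapStats:
    """Gap-time statistics for the first follow-up of ``label`` per user.

    The gap is measured in fractional days from the index date; "within
    24 h" means gap < 1.0 day.  An empty class yields an explicit empty
    result rather than an exception.
    """
    first = timelines.first_followups(label)
    gaps = first["gap_days"].to_numpy(dtype=float)
    if len(gaps) == 0:
        return GapStats(0, float("nan"), float("nan"), gaps)
    return GapStats(
        n_users=len(gaps),
        median_gap_days=median_low(gaps),
        fraction_within_24h=float((gaps < 1.0).mean()),
        gaps=gaps,
    )


def followed_by_pregnancy(timelines: Timelines, label: str) -> int:
    """Users whose first ``label`` query strictly precedes their first
    pregnancy-week query."""
    first_cls = timelines.first_followups(label).set_index("user_id")["timestamp"]
    first_preg = timelines.first_followups("pregnancy_week").set_index("user_id")["timestamp"]
    common = first_cls.index.intersection(first_preg.index)
    return int((first_cls.loc[common] < first_preg.loc[common]).sum())


def followup_summary(timelines: Timelines) -> dict[str, dict]:
    """Per-class follow-up incidence, gap statistics and ordering counts."""
    n_missed = timelines.n_users
    out: dict[str, dict] = {}
    for label in FOLLOWUP_LABELS:
        stats = gap_stats(timelines, label)
        entry = {
            "n_users_with_followup": stats.n_users,
            "fraction_of_missed_users": stats.n_users / n_missed if n_missed else float("nan"),
            "median_gap_days": stats.median_gap_days,
            "fraction_within_24h": stats.fraction_within_24h,
        }
        if label != "pregnancy_week":
            entry["n_before_first_pregnancy_query"] = followed_by_pregnancy(timelines, label)
        out[label] = entry
    return out
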