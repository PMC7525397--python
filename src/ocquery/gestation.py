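"""Gestational dating from pregnancy-week queries.

Each pregnancy-week query dates the first day of the last menstrual period
(LMP) as ``query date - 7 * reported week`` (start-of-reported-week
convention).  Recurrent queries from the same user give repeated LMP
estimates; their median is the user's consensus LMP and the median pairwise
absolute difference measures dating consistency.  A pregnancy is *timed to
the missed-pill cycle* when the index missed-OC query falls within one cycle
(default 28 days) at or after the consensus LMP; the offset of the index
date from the consensus LMP is then the conception-day estimate — the
missed-dose date as a proxy for the exposure day within the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd

from .linkage import Timelines

WEEK_MIN, WEEK_MAX = 1, 45


@dataclass
class InferredPregnancy:
    user_id: str
    n_queries: int
    consensus_lmp_day: float       # epoch days; half-integer for even counts
    lmp_consistency_days: Optional[float]
    timed: bool
    conception_day: Optional[float]


def infer_lmp(query_date: date, week: int) -> date:
    """First day of the LMP implied by a week-of-pregnancy mention."""
    if not WEEK_MIN <= week <= WEEK_MAX:
        raise ValueError(f"week {week} outside [{WEEK_MIN}, {WEEK_MAX}]")
    return query_date - timedelta(days=7 * int(week))


def lmp_consistency(lmp_days: np.ndarray) -> float:
    """Median over all unordered pairs of |difference| in days.

    Permutation-invariant; requires >= 2 estimates (NaN otherwise).
    """
    lmp_days = np.asarray(lmp_days, dtype=float)
    if len(lmp_days) < 2:
        return float("nan")
    diffs = [abs(a - b) for a, b in combinations(lmp_days, 2)]
    return float(np.median(diffs))


def classify_timed(
    consensus_lmp_day: float, index_day: float, cycle_length: int = 28
) -> tuple[bool, Optional[float]]:
    """(timed, conception day) for a consensus LMP and an index date.

    Timed iff 0 <= index - LMP < cycle_length days; the conception day is
    that offset, rounded to whole days.
    """
    offset = index_day - consensus_lmp_day
    if 0 <= offset < cycle_length:
        return True, float(np.rint(offset))
    return False, None


def _epoch_days(ts: np.ndarray) -> np.ndarray:
    return ts.astype("datetime64[s]").astype(float) / 86400.0


def infer_pregnancies(timelines: Timelines, cycle_length: int = 28) -> pd.DataFrame:
    """Per-user pregnancy table from pregnancy-week follow-up queries.

    One row per user with >= 1 pregnancy-week query at/after their index
    date: consensus LMP (median of per-query inferred LMPs), dating
    consistency, timed flag and conception day.
    """
    preg = timelines.followups[timelines.followups["label"] == "pregnancy_week"]
    cols = ["user_id", "n_queries", "consensus_lmp_day", "lmp_consistency_days",
            "timed", "conception_day"]
    if not len(preg):
        return pd.DataFrame(columns=cols)
    # LMP at day resolution: the query's calendar date minus 7*week
    q_day = np.floor(_epoch_days(preg["timestamp"].to_numpy()))
    lmp_day = q_day - 7.0 * preg["pregnancy_week"].to_numpy(dtype=float)
    tbl = pd.DataFrame({"user_id": preg["user_id"].to_numpy(), "lmp_day": lmp_day})
    index_day = np.floor(_epoch_days(timelines.index_dates.to_numpy()))
    index_by_user = pd.Series(index_day, index=timelines.index_dates.index)

    rows = []
    for user, grp in tbl.groupby("user_id", sort=False):
        lmps = grp["lmp_day"].to_numpy()
        consensus = float(np.median(lmps))
        timed, conception = classify_timed(
            consensus, float(index_by_user.loc[user]), cycle_length
        )
        rows.append(
            {
                "user_id": user,
                "n_queries": len(lmps),
                "consensus_lmp_day": consensus,
                "lmp_consistency_days": lmp_consistency(lmps),
                "timed": timed,
                "conception_day": conception if timed else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=cols)


def gestation_summary(pregnancies: pd.DataFrame) -> dict[str, float]:
    """Cohort-level dating statistics.

    The consistency statistic is the median over users (with >= 2 queries)
    of per-user median pairwise LMP differences.
    """
    if not len(pregnancies):
        return {
            "n_pregnancy_reporters": 0,
            "n_recurrent_reporters": 0,
            "timed_fraction": float("nan"),
            "conception_day_mean": float("nan"),
            "conception_day_sd": float("nan"),
            "lmp_consistency_median_days": float("nan"),
        }
    recurrent = pregnancies["lmp_consistency_days"].dropna()
    timed = pregnancies["timed"]
    conception = pregnancies.loc[timed, "conception_day"]
    return {
        "n_pregnancy_reporters": int(len(pregnancies)),
        "n_recurrent_reporters": int(len(recurrent)),
        "timed_fraction": float(timed.mean()),
        "conception_day_mean": float(conception.mean()) if len(conception) else float("nan"),
        "conception_day_sd": float(conception.std(ddof=1)) if len(conception) > 1 else float("nan"),
        "lmp_consistency_median_days": float(np.median(recurrent)) if len(recurrent) else float("nan"),
    }
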