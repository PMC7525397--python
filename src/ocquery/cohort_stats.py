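"""Descriptive and inferential cohort statistics.

Covers the tabulations and tests reported alongside the pregnancy-rate
analysis: dose-count and pill-type mention shares, the age/dose-count rank
correlation, age-band likelihood ratios with 2x2 chi-square tests, and the
two-rater Cohen's kappa utility used for label-audit agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, spearmanr

from .linkage import Timelines

# Age bands mirror the reporting scheme: <20, 20-24, ..., 40+.
AGE_BANDS = [(0, 19), (20, 24), (25, 29), (30, 34), (35, 39), (40, 200)]
UNDER_30 = (0, 29)
BAND_30_34 = (30, 34)


@dataclass
class AgeBandComparison:
    label: str
    band_a: tuple[int, int]
    band_b: Optional[tuple[int, int]]  # None = complement of band_a
    n_a: int
    n_b: int
    proportion_a: float
    proportion_b: float
    ratio: float
    chi2: float
    p_value: float


@dataclass
class AgreementResult:
    n_items: int
    observed_agreement: float
    expected_agreement: float
    kappa: float


def tabulate_missed(cohort: pd.DataFrame) -> dict:
    """Dose-count pmf, pill-type mention shares and placebo fraction.

    ``cohort`` has one row per missed-OC user (first missed query).  Pill
    shares can sum over 100%: users mentioning both a combined and a
    progestin-only product count in both categories.
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("empty cohort")
    doses = cohort["n_missed_doses"].to_numpy(dtype=float)
    dose_pmf = {
        "unspecified": float(np.isnan(doses).mean()),
        "1": float((doses == 1).mean()),
        "2": float((doses == 2).mean()),
        "3": float((doses == 3).mean()),
        "4plus": float((doses >= 4).mean()),
    }
    combined = cohort["pill_combined"].to_numpy(dtype=bool)
    progestin = cohort["pill_progestin"].to_numpy(dtype=bool)
    return {
        "n_users": n,
        "dose_count_pmf": dose_pmf,
        "pill_mention_shares": {
            "none": float((~combined & ~progestin).mean()),
            "combined": float(combined.mean()),
            "progestin_only": float(progestin.mean()),
        },
        "placebo_fraction": float(cohort["placebo_mentioned"].to_numpy(dtype=bool).mean()),
    }


def age_dose_correlation(
    ages: Sequence[float], doses: Sequence[float]
) -> tuple[Optional[float], Optional[float]]:
    """Spearman rank correlation between age and missed-dose count.

    Average ranks on ties; p-value from the large-sample approximation.
    Pairs with either value missing are dropped; an all-tied input yields
    (None, None).
    """
    ages = np.asarray(ages, dtype=float)
    doses = np.asarray(doses, dtype=float)
    ok = ~(np.isnan(ages) | np.isnan(doses))
    ages, doses = ages[ok], doses[ok]
    if len(ages) < 3:
        raise ValueError("need >= 3 complete (age, dose) pairs")
    if len(np.unique(ages)) == 1 or len(np.unique(doses)) == 1:
        return None, None
    rho, p = spearmanr(ages, doses)
    return float(rho), float(p)


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) for a 2x2 table."""
    stat, p, _, _ = chi2_contingency(np.asarray(table), correction=False)
    return float(stat), float(p)


def _band_mask(ages: np.ndarray, band: tuple[int, int]) -> np.ndarray:
    return (ages >= band[0]) & (ages <= band[1])


def age_band_ratio(
    timelines: Timelines,
    ages: pd.Series,
    label: str,
    band_a: tuple[int, int],
    band_b: Optional[tuple[int, int]] = None,
) -> AgeBandComparison:
    """Follow-up likelihood ratio between two age bands.

    ``ages``: per-user ages indexed by user_id; users with unknown age are
    excluded.  ``band_b=None`` compares against the complement of
    ``band_a`` among all aged users.  The chi-square is Pearson's on the
    2x2 band x has-follow-up table.
    """
    aged = ages.dropna()
    aged = aged[aged.index.isin(timelines.index_dates.index)]
    age_arr = aged.to_numpy(dtype=float)
    mask_a = _band_mask(age_arr, band_a)
    mask_b = _band_mask(age_arr, band_b) if band_b is not None else ~mask_a
    if not mask_a.any() or not mask_b.any():
        empty = "A" if not mask_a.any() else "B"
        raise ValueError(f"age band {empty} contains no users with known age")

    followers = set(timelines.first_followups(label)["user_id"])
    has = aged.index.isin(followers)
    a_yes, a_no = int((has & mask_a).sum()), int((~has & mask_a).sum())
    b_yes, b_no = int((has & mask_b).sum()), int((~has & mask_b).sum())
    prop_a = a_yes / (a_yes + a_no)
    prop_b = b_yes / (b_yes + b_no)
    chi2, p = chi2_2x2([[a_yes, a_no], [b_yes, b_no]])
    return AgeBandComparison(
        label=label,
        band_a=band_a,
        band_b=band_b,
        n_a=a_yes + a_no,
        n_b=b_yes + b_no,
        proportion_a=prop_a,
        proportion_b=prop_b,
        ratio=prop_a / prop_b if prop_b > 0 else float("inf"),
        chi2=chi2,
        p_value=p,
    )


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> AgreementResult:
    """Two-rater Cohen's kappa with marginal-product expected agreement.

    Symmetric in its arguments.  When expected agreement is 1 (both raters
    constant), kappa is reported as 0 if observed agreement is also 1.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError(f"label lists differ in length: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("empty label lists")
    n = len(a)
    po = float((a == b).mean())
    cats = np.union1d(a, b)
    pe = float(sum((a == c).mean() * (b == c).mean() for c in cats))
    if pe >= 1.0:
        kappa = 0.0 if po >= 1.0 else float("-inf")
    else:
        kappa = (po - pe) / (1.0 - pe)
    return AgreementResult(n_items=n, observed_agreement=po,
                           expected_agreement=pe, kappa=float(kappa))
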