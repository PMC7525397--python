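"""Observability weights and censoring-corrected pregnancy rates."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocquery import (
    ScenarioConfig,
    WeekDistribution,
    analyze,
    compute_weight,
    compute_weights,
    estimate_week_distribution,
    generate_cohort,
    subgroup_rates,
    weighted_pregnancy_rate,
)

from conftest import make_classified


def test_week_distribution_from_counts():
    dist = WeekDistribution.from_counts([4, 4, 8, 12])
    assert dist.as_dict() == {4: 0.5, 8: 0.25, 12: 0.25}
    assert WeekDistribution.from_counts([10, 10]).as_dict() == {10: 1.0}


def test_week_distribution_validates():
    with pytest.raises(ValueError):
        WeekDistribution(np.array([4, 8]), np.array([0.6, 0.6]))


def test_estimate_week_distribution():
    classified = make_classified(
        [
            ("a", "2018-02-01", "pregnancy_week", 4),
            ("a", "2018-03-01", "pregnancy_week", 8),
            ("b", "2018-02-01", "pregnancy_week", 4),
            ("b", "2018-02-02", "other"),
        ]
    )
    dist = estimate_week_distribution(classified)
    assert dist.as_dict() == {4: 2 / 3, 8: 1 / 3}


def test_estimate_week_distribution_empty_raises():
    classified = make_classified([("a", "2018-01-01", "missed_oc")])
    with pytest.raises(ValueError, match="prior"):
        estimate_week_distribution(classified)


def test_weight_full_term_observable_is_one():
    """A January index date sees the whole support: weight exactly 1."""
    weeks = np.arange(4, 41)
    dist = WeekDistribution(weeks, np.full(len(weeks), 1 / len(weeks)))
    assert compute_weight("2018-01-15", dist, "2018-12-31") == pytest.approx(1.0)


def test_weight_december_user():
    """Uniform support 4..39; from Dec 1 only week 4 (Dec 29) is observable."""
    weeks = np.arange(4, 40)
    dist = WeekDistribution(weeks, np.full(36, 1 / 36))
    w = compute_weight("2018-12-01", dist, "2018-12-31")
    assert w == pytest.approx(1 / 36)


def test_weight_zero_when_no_week_observable():
    dist = WeekDistribution(np.array([4]), np.array([1.0]))
    assert compute_weight("2018-12-31", dist, "2018-12-31") == 0.0


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(1, 45), min_size=1, max_size=8, unique=True),
    st.integers(0, 364),
)
def test_weight_matches_day_enumeration_oracle(weeks, index_offset):
    """compute_weight equals brute-force day-by-day calendar enumeration."""
    weeks = sorted(weeks)
    probs = np.full(len(weeks), 1.0 / len(weeks))
    dist = WeekDistribution(np.array(weeks), probs)
    index = date(2018, 1, 1) + timedelta(days=index_offset)
    end = date(2018, 12, 31)
    expected = sum(
        p for k, p in zip(weeks, probs) if index + timedelta(days=7 * k) <= end
    )
    assert compute_weight(index.isoformat(), dist, "2018-12-31") == pytest.approx(expected)


def test_weight_non_increasing_in_index_date():
    weeks = np.arange(4, 21)
    dist = WeekDistribution(weeks, np.full(len(weeks), 1 / len(weeks)))
    dates = pd.Series(pd.date_range("2018-01-01", "2018-12-31", freq="D"))
    w = compute_weights(dates, dist, "2018-12-31")
    assert (np.diff(w.to_numpy()) <= 1e-12).all()


def test_weighted_rate_arithmetic():
    res = weighted_pregnancy_rate(np.array([1.0, 1.0]), np.array([True, False]))
    assert res["weighted_rate"] == pytest.approx(0.5)
    res = weighted_pregnancy_rate(np.array([1.0, 0.5, 0.5]), np.array([True, False, False]))
    assert res["weighted_rate"] == pytest.approx(0.5)
    assert res["unweighted_rate"] == pytest.approx(1 / 3)
    assert res["effective_n"] == pytest.approx(2.0)


def test_weight_floor_applies():
    res = weighted_pregnancy_rate(np.array([0.0, 1.0]), np.array([False, True]), floor=0.01)
    assert res["effective_n"] == pytest.approx(1.01)


def test_horvitz_thompson_variant():
    res = weighted_pregnancy_rate(
        np.array([0.5, 1.0]), np.array([True, False]), estimator="horvitz_thompson"
    )
    assert res["weighted_rate"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        weighted_pregnancy_rate(np.array([1.0]), np.array([True]), estimator="nope")


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.floats(0.05, 1.0), st.booleans()), min_size=1, max_size=30
    )
)
def test_weighting_never_lowers_the_rate(users):
    """Censoring weights shrink the denominator only: weighted >= unweighted."""
    weights = np.array([u[0] for u in users])
    pregnant = np.array([u[1] for u in users])
    res = weighted_pregnancy_rate(weights, pregnant)
    assert res["weighted_rate"] >= res["unweighted_rate"] - 1e-12


def test_uncensored_scenario_weighted_equals_unweighted():
    """All index dates in January: every weight is 1 and the correction
    vanishes identically."""
    cfg = ScenarioConfig(n_users=2500, seed=21, index_window=("2018-01-01", "2018-01-31"))
    log, _ = generate_cohort(cfg)
    report = analyze(log, window_end=cfg.window_end)
    overall = report["rates"]["overall"]
    assert overall["effective_n"] == pytest.approx(overall["n_users"])
    assert overall["weighted_rate"] == pytest.approx(overall["unweighted_rate"])


def _toy_cohort():
    return pd.DataFrame(
        {
            "weight": [1.0, 1.0, 1.0, 1.0],
            "pregnant": [True, False, True, False],
            "pill_combined": [True, True, False, False],
            "pill_progestin": [False, False, True, True],
            "placebo_mentioned": [False, False, False, False],
            "n_missed_doses": [2.0, 2.0, np.nan, np.nan],
        }
    )


def test_subgroup_rates_symmetry_and_flags():
    """Identical users split into two labelled halves get equal rates."""
    rates = subgroup_rates(_toy_cohort(), "pill_type", min_stratum_size=1)
    by = rates.set_index("stratum")
    assert by.loc["combined", "weighted_rate"] == by.loc["progestin_only", "weighted_rate"]
    rates = subgroup_rates(_toy_cohort(), "dose_count_2plus", min_stratum_size=3)
    by = rates.set_index("stratum")
    assert by.loc["two_plus", "n_users"] == 2
    assert bool(by.loc["two_plus", "small_stratum"]) is True


def test_subgroup_rates_unknown_grouping():
    with pytest.raises(ValueError, match="unknown grouping"):
        subgroup_rates(_toy_cohort(), "age")
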