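"""Tabulations, rank correlation, 2x2 chi-square, Cohen's kappa."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocquery import age_band_ratio, age_dose_correlation, build_timelines, cohens_kappa, tabulate_missed
from ocquery.cohort_stats import BAND_30_34, UNDER_30, chi2_2x2

from conftest import make_classified


def _cohort(n=10, doses2=2, both=0):
    doses = [2.0] * doses2 + [np.nan] * (n - doses2)
    combined = [True] * both + [False] * (n - both)
    progestin = [True] * both + [False] * (n - both)
    return pd.DataFrame(
        {
            "n_missed_doses": doses,
            "pill_combined": combined,
            "pill_progestin": progestin,
            "placebo_mentioned": [False] * n,
        }
    )


def test_tabulate_missed_shares():
    tab = tabulate_missed(_cohort(n=10, doses2=2))
    assert tab["dose_count_pmf"]["2"] == pytest.approx(0.2)
    assert tab["dose_count_pmf"]["unspecified"] == pytest.approx(0.8)


def test_tabulate_double_mention_counts_in_both():
    """A user mentioning both pill kinds counts in both categories, so the
    shares can sum over 100%."""
    tab = tabulate_missed(_cohort(n=4, both=2))
    shares = tab["pill_mention_shares"]
    assert shares["combined"] == shares["progestin_only"] == pytest.approx(0.5)
    assert shares["none"] == pytest.approx(0.5)
    assert shares["combined"] + shares["progestin_only"] + shares["none"] > 1


def test_tabulate_empty_raises():
    with pytest.raises(ValueError):
        tabulate_missed(_cohort(n=0))


@pytest.mark.parametrize(
    ("ages", "doses", "rho"),
    [
        ([20, 25, 30], [1, 2, 3], 1.0),
        ([20, 25, 30], [3, 2, 1], -1.0),
        # ranks: ages 1,2,3,4; doses 1.5,1.5,3.5,3.5 -> Pearson of ranks
        ([20, 21, 22, 23], [1, 1, 2, 2], 2 / np.sqrt(5)),
    ],
)
def test_age_dose_correlation(ages, doses, rho):
    got, p = age_dose_correlation(ages, doses)
    assert got == pytest.approx(rho)
    assert 0 <= p <= 1


def test_age_dose_correlation_degenerate():
    assert age_dose_correlation([20, 20, 20], [1, 2, 3]) == (None, None)
    with pytest.raises(ValueError):
        age_dose_correlation([20, 25], [1, 2])


def test_chi2_closed_form_example():
    """[[30,70],[20,80]]: chi2 = 200*(30*80-70*20)^2/(100*100*50*150)."""
    stat, p = chi2_2x2([[30, 70], [20, 80]])
    assert stat == pytest.approx(200 * (30 * 80 - 70 * 20) ** 2 / (100 * 100 * 50 * 150))
    assert stat == pytest.approx(8 / 3)
    assert 0 < p < 1


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.tuples(*[st.integers(1, 200) for _ in range(4)]))
def test_chi2_matches_closed_form_oracle(cells):
    a, b, c, d = cells
    n = a + b + c + d
    oracle = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    stat, _ = chi2_2x2([[a, b], [c, d]])
    assert stat == pytest.approx(oracle, rel=1e-9)


def _band_timelines(n_a=100, yes_a=30, n_b=100, yes_b=20):
    rows = []
    ages = {}
    for i in range(n_a):
        uid = f"a{i}"
        ages[uid] = 32  # inside 30-34
        rows.append((uid, "2018-01-01", "missed_oc"))
        if i < yes_a:
            rows.append((uid, "2018-01-10", "miscarriage"))
    for i in range(n_b):
        uid = f"b{i}"
        ages[uid] = 22
        rows.append((uid, "2018-01-01", "missed_oc"))
        if i < yes_b:
            rows.append((uid, "2018-01-10", "miscarriage"))
    return build_timelines(make_classified(rows)), pd.Series(ages, dtype=float)


def test_age_band_ratio():
    tl, ages = _band_timelines()
    cmp = age_band_ratio(tl, ages, "miscarriage", BAND_30_34)
    assert cmp.ratio == pytest.approx(1.5)
    assert cmp.chi2 == pytest.approx(8 / 3)
    assert cmp.n_a == cmp.n_b == 100


def test_age_band_ratio_identical_bands():
    tl, ages = _band_timelines(yes_a=20, yes_b=20)
    cmp = age_band_ratio(tl, ages, "miscarriage", BAND_30_34)
    assert cmp.ratio == pytest.approx(1.0)
    assert cmp.chi2 == pytest.approx(0.0)


def test_age_band_ratio_empty_band_raises():
    tl, ages = _band_timelines(n_a=5)
    under_20 = (0, 15)
    with pytest.raises(ValueError, match="band A"):
        age_band_ratio(tl, ages, "miscarriage", under_20)


def test_age_band_ratio_excludes_unknown_ages():
    tl, ages = _band_timelines()
    ages_with_missing = ages.copy()
    ages_with_missing.iloc[:10] = np.nan
    cmp = age_band_ratio(tl, ages_with_missing, "miscarriage", BAND_30_34)
    assert cmp.n_a == 90


def test_kappa_identical_labels():
    res = cohens_kappa(["y", "n", "y"], ["y", "n", "y"])
    assert res.kappa == pytest.approx(1.0)
    assert res.observed_agreement == 1.0


def test_kappa_hand_computed_example():
    """11 both-yes, 7 both-no, 1+1 discordant: po=0.9, pe=0.52, kappa=0.79167."""
    a = ["y"] * 11 + ["n"] * 7 + ["y", "n"]
    b = ["y"] * 11 + ["n"] * 7 + ["n", "y"]
    res = cohens_kappa(a, b)
    assert res.observed_agreement == pytest.approx(0.9)
    assert res.expected_agreement == pytest.approx(0.52)
    assert res.kappa == pytest.approx((0.9 - 0.52) / 0.48)


def test_kappa_constant_rater_conventions():
    # one rater constant with partial agreement: po == pe -> kappa 0
    res = cohens_kappa(["y", "y", "y", "y"], ["y", "y", "n", "n"])
    assert res.kappa == pytest.approx(0.0)
    # both raters constant and identical: pe = 1, kappa 0 by convention
    assert cohens_kappa(["y", "y"], ["y", "y"]).kappa == 0.0


def test_kappa_length_mismatch():
    with pytest.raises(ValueError, match="length"):
        cohens_kappa(["y"], ["y", "n"])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=40))
def test_kappa_symmetric_and_matches_sklearn(pairs):
    from sklearn.metrics import cohen_kappa_score

    a = [p[0] for p in pairs]
    b = [p[1] for p in pairs]
    res = cohens_kappa(a, b)
    assert res.kappa == pytest.approx(cohens_kappa(b, a).kappa, nan_ok=True)
    if res.expected_agreement < 1.0:
        assert res.kappa == pytest.approx(cohen_kappa_score(a, b), abs=1e-9)
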