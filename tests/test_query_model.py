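"""Rule-based classifier: trigger phrases, exclusions, precedence, extraction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocquery import classify_frame, classify_query, extract_missed_attrs, extract_pregnancy_week


@pytest.mark.parametrize(
    ("text", "label"),
    [
        # missed-OC triggers: a miss-verb variant plus an OC term or brand
        ("i forgot my birth control pill yesterday", "missed_oc"),
        ("skipped my yaz pill this morning", "missed_oc"),
        ("MISSED MY MINIPILL", "missed_oc"),
        ("forgot to take my contraceptive", "missed_oc"),
        ("forgetting micronor doses", "missed_oc"),
        # pregnancy-week: both "week" and a pregnancy term plus a week number
        ("what to expect on week 21 of pregnancy", "pregnancy_week"),
        ("8 weeks pregnant cramps", "pregnancy_week"),
        ("weeks until pregnancy test works", "other"),  # no attached number
        ("week 50 of pregnancy", "other"),  # out of the 1..45 range
        # emergency contraception, with exclusions
        ("plan b price near me", "emergency_contraception"),
        ("how does the morning after pill work", "emergency_contraception"),
        ("morning after pill legislation vote", "other"),
        # miscarriage trigger phrases
        ("bleeding after miscarriage", "miscarriage"),
        ("recovery post miscarriage", "miscarriage"),
        ("i had a miscarriage what happens next", "miscarriage"),
        ("miscarriage statistics", "other"),  # bare word is not a trigger
        # abortion, with exclusions
        ("abortion clinic near me", "abortion"),
        ("abortion law debate 2018", "other"),
        ("celebrity abortion interview", "other"),
        # non-triggers
        ("   ", "other"),
        ("missed flight compensation", "other"),
        ("skipped breakfast effects", "other"),
        ("weather tomorrow", "other"),
    ],
)
def test_classify_examples(text, label, lexicon):
    assert classify_query(text, lexicon).label == label


@pytest.mark.parametrize(
    ("text", "label"),
    [
        # a missed-pill mention wins over any other class
        ("forgot my birth control pill week 8 of pregnancy", "missed_oc"),
        ("missed my birth control should i take plan b", "missed_oc"),
        # pregnancy-week outranks EC/miscarriage/abortion
        ("plan b failed now 6 weeks pregnant", "pregnancy_week"),
        # EC outranks miscarriage, miscarriage outranks abortion
        ("plan b after miscarriage", "emergency_contraception"),
        ("abortion or miscarriage after miscarriage symptoms", "miscarriage"),
    ],
)
def test_precedence(text, label, lexicon):
    assert classify_query(text, lexicon).label == label


_words = st.sampled_from(
    ["missed", "my", "birth", "control", "pill", "week", "8", "of", "pregnancy",
     "plan", "b", "abortion", "after", "miscarriage", "law", "recipe", "the"]
)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(_words, min_size=0, max_size=8))
def test_case_insensitive_and_total(tokens):
    """f(text) == f(UPPER(text)) and exactly one label is always returned."""
    text = " ".join(tokens)
    lower = classify_query(text)
    upper = classify_query(text.upper())
    assert lower.label == upper.label
    assert lower.label in {
        "missed_oc", "miscarriage", "abortion", "emergency_contraception",
        "pregnancy_week", "other",
    }


@pytest.mark.parametrize(
    ("text", "pill_type", "n_doses", "placebo"),
    [
        ("forgot 2 birth control pills in a row", "unspecified", 2, False),
        ("missed my placebo pill does it matter", "unspecified", None, True),
        ("skipped a minipill dose", "progestin_only", None, False),
        ("missed two doses of birth control", "unspecified", 2, False),
        ("forgot 3 yaz pills", "combined", 3, False),
        ("missed my sugar pill week", "unspecified", None, True),
        ("missed 1 junel and micronor pills", "combined", 1, False),
        ("skipped my errin pill", "progestin_only", None, False),
    ],
)
def test_extract_missed_attrs(text, pill_type, n_doses, placebo, lexicon):
    assert extract_missed_attrs(text, lexicon) == (pill_type, n_doses, placebo)


@pytest.mark.parametrize(
    ("text", "week"),
    [
        ("pregnancy week 10 symptoms", 10),
        ("21 weeks pregnant what to expect", 21),
        ("weeks until pregnancy test works", None),
        ("week 46 of pregnancy", None),
        ("1st week of pregnancy", 1),
    ],
)
def test_extract_pregnancy_week(text, week):
    assert extract_pregnancy_week(text) == week


def test_frame_and_record_paths_agree(medium_cohort, lexicon):
    """The vectorised classifier applies exactly the per-record rules."""
    _, log, _ = medium_cohort
    sample = log.sample(1500, random_state=0)
    frame_labels = classify_frame(sample, lexicon)["label"]
    record_labels = [classify_query(t, lexicon).label for t in sample["text"]]
    assert list(frame_labels) == record_labels


def test_attribute_columns_respect_labels(medium_cohort, lexicon):
    """Week only on pregnancy_week rows; missed attributes only on missed_oc."""
    _, log, _ = medium_cohort
    classified = classify_frame(log, lexicon)
    not_preg = classified["label"] != "pregnancy_week"
    assert classified.loc[not_preg, "pregnancy_week"].isna().all()
    not_missed = classified["label"] != "missed_oc"
    assert classified.loc[not_missed, "n_missed_doses"].isna().all()
    assert not classified.loc[not_missed, "placebo_mentioned"].any()
    assert classified.loc[not_missed, "pill_type"].isna().all()
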