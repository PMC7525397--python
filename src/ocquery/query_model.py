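"""Domain types and the rule-based five-class query classifier.

Classes
-------
``missed_oc``
    A missed/skipped/forgotten dose of an oral contraceptive: a miss-verb
    variant together with an OC brand name or a generic OC term
    ("birth control", "contraceptive", "minipill").
``miscarriage``
    "after miscarriage", "post miscarriage" or "i had a miscarriage".
``abortion``
    "abortion", excluding legislation / debate / celebrity queries.
``emergency_contraception``
    "plan b" or "morning after pill", with the same exclusions.
``pregnancy_week``
    "week" and a pregnancy term with an extractable week number in 1..45
    (e.g. "what to expect on week 21 of pregnancy").

When several rules fire, precedence is
missed_oc > pregnancy_week > emergency_contraception > miscarriage >
abortion: a query mentioning a missed pill is the index event of interest,
and a week-of-pregnancy mention outranks the remaining classes.

Both a per-record API (:func:`classify_query`) and a vectorised DataFrame
API (:func:`classify_frame`) are provided; they apply identical rules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

import numpy as np
import pandas as pd

from .lexicon import Lexicon

LABELS = [
    "missed_oc",
    "miscarriage",
    "abortion",
    "emergency_contraception",
    "pregnancy_week",
    "other",
]

FOLLOWUP_LABELS = [
    "miscarriage",
    "abortion",
    "emergency_contraception",
    "pregnancy_week",
]

WEEK_MIN, WEEK_MAX = 1, 45

_PUNCT_RE = re.compile(r"[^\w\s-]")
_WS_RE = re.compile(r"\s+")

_NUMBER_WORDS = {
    "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
    "six": 6, "seven": 7, "eight": 8, "nine": 9,
}

# A count adjacent (within three tokens) to a pill/dose term.
_DOSE_RE = re.compile(
    r"\b(\d{1,2}|one|two|three|four|five|six|seven|eight|nine)"
    r"\s+(?:[\w-]+\s+){0,3}(?:pills?|doses?)\b"
)

# "week 21" / "21 weeks" / "21st week"
_WEEK_RE = re.compile(r"\bweeks?\s+(\d{1,2})\b|\b(\d{1,2})(?:st|nd|rd|th)?\s+weeks?\b")

_PREGNANCY_RE = re.compile(r"\bpregnan\w*\b")


def normalize_text(text: str) -> str:
    """Lowercase, strip punctuation except hyphens, collapse whitespace."""
    text = _PUNCT_RE.sub(" ", text.lower())
    return _WS_RE.sub(" ", text).strip()


@dataclass
class QueryRecord:
    """One raw query-log row."""

    user_id: str
    timestamp: datetime
    text: str
    age: Optional[int] = None
    gender: str = "unknown"


@dataclass
class ClassifiedQuery:
    """A query record plus its class label and extracted attributes.

    ``pill_type``, ``n_missed_doses`` and ``placebo_mentioned`` are
    meaningful only for ``missed_oc`` queries; ``pregnancy_week`` only for
    pregnancy-week queries.
    """

    record: QueryRecord
    label: str
    pill_type: Optional[str] = None
    n_missed_doses: Optional[int] = None
    placebo_mentioned: bool = False
    pregnancy_week: Optional[int] = None


@dataclass
class UserTimeline:
    """Time-ordered classified queries for one user.

    ``index_date`` is the timestamp of the first missed_oc query (None when
    the user never issued one); ties are broken by stable input order.
    """

    user_id: str
    queries: list[ClassifiedQuery] = field(default_factory=list)

    @property
    def index_date(self) -> Optional[datetime]:
        stamps = [q.record.timestamp for q in self.queries if q.label == "missed_oc"]
        return min(stamps) if stamps else None


def extract_pregnancy_week(text: str) -> Optional[int]:
    """First integer in [1, 45] syntactically attached to "week(s)"."""
    for m in _WEEK_RE.finditer(normalize_text(text)):
        token = m.group(1) or m.group(2)
        week = int(token)
        if WEEK_MIN <= week <= WEEK_MAX:
            return week
    return None


def extract_missed_attrs(
    text: str, lexicon: Lexicon
) -> tuple[str, Optional[int], bool]:
    """(pill_type, n_missed_doses, placebo_mentioned) for a missed_oc query.

    ``pill_type`` is "combined", "progestin_only" or "unspecified" (a query
    mentioning both kinds of brand reports "combined" here; frame-level
    tabulations keep both flags).  Counts are parsed from digits or the
    number words one..nine adjacent to pill/dose terms.
    """
    norm = normalize_text(text)
    combined = bool(lexicon.combined_re.search(norm))
    progestin = bool(lexicon.progestin_re.search(norm))
    if combined:
        pill_type = "combined"
    elif progestin:
        pill_type = "progestin_only"
    else:
        pill_type = "unspecified"
    n_doses: Optional[int] = None
    m = _DOSE_RE.search(norm)
    if m:
        token = m.group(1)
        n_doses = _NUMBER_WORDS.get(token) if token in _NUMBER_WORDS else int(token)
        if n_doses is not None and n_doses <= 0:
            n_doses = None
    placebo = bool(lexicon.placebo_re.search(norm))
    return pill_type, n_doses, placebo


def _label_for(norm: str, lexicon: Lexicon) -> str:
    if lexicon.missed_verb_re.search(norm) and lexicon.oc_term_re.search(norm):
        return "missed_oc"
    if _PREGNANCY_RE.search(norm) and _WEEK_RE.search(norm):
        for m in _WEEK_RE.finditer(norm):
            week = int(m.group(1) or m.group(2))
            if WEEK_MIN <= week <= WEEK_MAX:
                return "pregnancy_week"
    excluded = bool(lexicon.exclusion_re.search(norm))
    if lexicon.ec_re.search(norm) and not excluded:
        return "emergency_contraception"
    if lexicon.miscarriage_re.search(norm):
        return "miscarriage"
    if lexicon.abortion_re.search(norm) and not excluded:
        return "abortion"
    return "other"


def classify_query(text: str, lexicon: Optional[Lexicon] = None) -> ClassifiedQuery:
    """Classify a single query string; never raises on arbitrary text."""
    if lexicon is None:
        lexicon = Lexicon.default()
    record = QueryRecord(user_id="", timestamp=datetime.min, text=text)
    norm = normalize_text(text)
    if not norm:
        return ClassifiedQuery(record=record, label="other")
    label = _label_for(norm, lexicon)
    out = ClassifiedQuery(record=record, label=label)
    if label == "missed_oc":
        out.pill_type, out.n_missed_doses, out.placebo_mentioned = extract_missed_attrs(
            text, lexicon
        )
    elif label == "pregnancy_week":
        out.pregnancy_week = extract_pregnancy_week(text)
    return out


def _contains(norm: pd.Series, pattern: re.Pattern) -> pd.Series:
    return norm.str.contains(pattern, regex=True)


def classify_frame(log: pd.DataFrame, lexicon: Optional[Lexicon] = None) -> pd.DataFrame:
    """Vectorised classification of a query-log DataFrame.

    Expects columns ``user_id``, ``timestamp``, ``text`` (plus optional
    ``age``, ``gender``).  Returns a copy with added columns ``label``,
    ``pill_type``, ``pill_combined``, ``pill_progestin``, ``n_missed_doses``,
    ``placebo_mentioned`` and ``pregnancy_week``.  Rows with empty text are
    labelled "other".
    """
    if lexicon is None:
        lexicon = Lexicon.default()
    out = log.copy()
    norm = out["text"].fillna("").map(normalize_text)

    missed = _contains(norm, lexicon.missed_verb_re) & _contains(norm, lexicon.oc_term_re)

    week_extracted = norm.str.extractall(_WEEK_RE)
    week_val = pd.Series(np.nan, index=out.index)
    if len(week_extracted):
        w = week_extracted[0].fillna(week_extracted[1]).astype(float)
        w = w.where((w >= WEEK_MIN) & (w <= WEEK_MAX))
        first = w.dropna().groupby(level=0).first()
        week_val.loc[first.index] = first
    preg = _contains(norm, _PREGNANCY_RE) & week_val.notna()

    excluded = _contains(norm, lexicon.exclusion_re)
    ec = _contains(norm, lexicon.ec_re) & ~excluded
    misc = _contains(norm, lexicon.miscarriage_re)
    abort = _contains(norm, lexicon.abortion_re) & ~excluded

    label = np.select(
        [missed, preg, ec, misc, abort],
        ["missed_oc", "pregnancy_week", "emergency_contraception", "miscarriage", "abortion"],
        default="other",
    )
    out["label"] = label

    is_missed = out["label"] == "missed_oc"
    combined = _contains(norm, lexicon.combined_re) & is_missed
    progestin = _contains(norm, lexicon.progestin_re) & is_missed
    out["pill_combined"] = combined
    out["pill_progestin"] = progestin
    pill_type = np.select(
        [combined, progestin], ["combined", "progestin_only"], default="unspecified"
    )
    out["pill_type"] = np.where(is_missed, pill_type, None)

    dose_tokens = norm.str.extract(_DOSE_RE, expand=False)
    doses = dose_tokens.map(lambda t: _NUMBER_WORDS.get(t, t) if isinstance(t, str) else t)
    out["n_missed_doses"] = pd.to_numeric(doses, errors="coerce").where(is_missed)
    out["placebo_mentioned"] = _contains(norm, lexicon.placebo_re) & is_missed
    out["pregnancy_week"] = week_val.where(out["label"] == "pregnancy_week")
    return out


def classification_counts(classified: pd.DataFrame) -> dict[str, int]:
    counts = classified["label"].value_counts().to_dict()
    return {label: int(counts.get(label, 0)) for label in LABELS}
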