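"""Keyword lexicon driving the rule-based query classifier.

The classifier is deliberately dumb: five query classes, each defined by a
handful of trigger phrases plus exclusion lists, applied to lowercased,
punctuation-stripped text.  All of the trigger/exclusion vocabulary lives in
a :class:`Lexicon` so that brand lists and exclusion lists can be audited and
edited without touching code.  A YAML file with any subset of the keys
overrides the built-in defaults.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields

import yaml

# Brand lists are editable placeholders: common US combined-pill and
# progestin-only brand names.  The analysis statistics do not depend on the
# exact contents, only on the combined/progestin split.
DEFAULT_COMBINED_BRANDS = [
    "yaz",
    "yasmin",
    "alesse",
    "levora",
    "sprintec",
    "estarylla",
    "ortho tri-cyclen",
    "lo loestrin",
    "seasonique",
    "trinessa",
    "apri",
    "junel",
]

DEFAULT_PROGESTIN_BRANDS = [
    "micronor",
    "camila",
    "errin",
    "heather",
    "nora-be",
    "jolivette",
    "norethindrone",
]

# Generic oral-contraceptive terms that qualify a missed-dose query even
# without a brand name.
DEFAULT_GENERIC_OC_TERMS = [
    "birth control",
    "contraceptive",
    "contraceptives",
    "minipill",
    "mini pill",
]

DEFAULT_MISSED_VERBS = [
    "miss", "missed", "misses", "missing",
    "skip", "skipped", "skipping", "skips",
    "forgot", "forgotten", "forget", "forgets", "forgetting",
]

DEFAULT_MISCARRIAGE_PHRASES = [
    "after miscarriage",
    "post miscarriage",
    "i had a miscarriage",
]

DEFAULT_EC_PHRASES = ["plan b", "morning after pill"]

# Queries about legislation, political debate, news or celebrities are not
# expressions of personal concern and are excluded from the abortion and
# emergency-contraception classes.
DEFAULT_EXCLUSION_TERMS = [
    "law", "laws", "legal", "illegal", "legislation", "ban", "bans",
    "debate", "court", "supreme court", "senate", "congress", "bill",
    "ruling", "vote", "news", "history", "statistics", "rate", "rates",
    "celebrity", "celebrities", "protest", "rights", "movie", "documentary",
]


@dataclass
class Lexicon:
    """Keyword lists for the five query classes, plus compiled patterns."""

    missed_verbs: list[str] = field(default_factory=lambda: list(DEFAULT_MISSED_VERBS))
    generic_oc_terms: list[str] = field(default_factory=lambda: list(DEFAULT_GENERIC_OC_TERMS))
    combined_brands: list[str] = field(default_factory=lambda: list(DEFAULT_COMBINED_BRANDS))
    progestin_brands: list[str] = field(default_factory=lambda: list(DEFAULT_PROGESTIN_BRANDS))
    miscarriage_phrases: list[str] = field(default_factory=lambda: list(DEFAULT_MISCARRIAGE_PHRASES))
    ec_phrases: list[str] = field(default_factory=lambda: list(DEFAULT_EC_PHRASES))
    exclusion_terms: list[str] = field(default_factory=lambda: list(DEFAULT_EXCLUSION_TERMS))

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not isinstance(value, list) or not value:
                raise ValueError(f"lexicon entry {f.name!r} must be a non-empty list")
        self._compile()

    def _compile(self) -> None:
        def alt(words: list[str]) -> str:
            return "|".join(re.escape(w) for w in sorted(words, key=len, reverse=True))

        oc_terms = self.generic_oc_terms + self.combined_brands + self.progestin_brands
        self.missed_verb_re = re.compile(rf"\b(?:{alt(self.missed_verbs)})\b")
        self.oc_term_re = re.compile(rf"\b(?:{alt(oc_terms)})\b")
        self.combined_re = re.compile(rf"\b(?:{alt(self.combined_brands)})\b")
        progestin = self.progestin_brands + ["minipill", "mini pill"]
        self.progestin_re = re.compile(rf"\b(?:{alt(progestin)})\b")
        self.miscarriage_re = re.compile(rf"\b(?:{alt(self.miscarriage_phrases)})\b")
        self.ec_re = re.compile(rf"\b(?:{alt(self.ec_phrases)})\b")
        self.abortion_re = re.compile(r"\babortions?\b")
        self.exclusion_re = re.compile(rf"\b(?:{alt(self.exclusion_terms)})\b")
        self.placebo_re = re.compile(r"\b(?:placebo|sugar pill)\b")

    @classmethod
    def default(cls) -> "Lexicon":
        return cls()

    @classmethod
    def from_yaml(cls, path: str) -> "Lexicon":
        """Load a lexicon; keys absent from the file keep their defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown lexicon keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
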