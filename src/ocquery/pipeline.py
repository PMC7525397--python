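"""End-to-end orchestration: classify -> link -> date -> weight -> report.

The analysis report is a nested, JSON-serialisable dict whose every number
is recomputable from the input log and configuration; it embeds a cohort
hash (user id + index date) so recovery runs can detect mismatched inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import censoring, cohort_stats, gestation, linkage
from .lexicon import Lexicon
from .query_model import classification_counts, classify_frame
from .synthetic_cohort import ScenarioConfig

logger = logging.getLogger(__name__)


def build_cohort_table(
    classified: pd.DataFrame,
    timelines: linkage.Timelines,
    dist: censoring.WeekDistribution,
    window_end,
) -> pd.DataFrame:
    """One row per missed-OC user: attributes of the first missed query,
    observability weight, and the observed-pregnancy indicator."""
    missed = classified[classified["label"] == "missed_oc"].sort_values(
        "timestamp", kind="stable"
    )
    first = missed.groupby("user_id", sort=True).first()
    weights = censoring.compute_weights(timelines.index_dates, dist, window_end)
    pregnant_users = set(timelines.first_followups("pregnancy_week")["user_id"])

    ages = classified.groupby("user_id")["age"].first() if "age" in classified else None
    cohort = pd.DataFrame(
        {
            "index_date": timelines.index_dates,
            "weight": weights,
            "pregnant": timelines.index_dates.index.isin(pregnant_users),
            "pill_combined": first["pill_combined"].astype(bool),
            "pill_progestin": first["pill_progestin"].astype(bool),
            "placebo_mentioned": first["placebo_mentioned"].astype(bool),
            "n_missed_doses": first["n_missed_doses"].astype(float),
        }
    )
    cohort["age"] = ages.astype(float) if ages is not None else np.nan
    return cohort


def _cohort_hash(timelines: linkage.Timelines) -> str:
    lines = sorted(
        f"{u}:{pd.Timestamp(t).isoformat()}" for u, t in timelines.index_dates.items()
    )
    return hashlib.sha256("\n".join(lines).encode()).hexdigest()


def analyze(
    log: pd.DataFrame,
    lexicon: Optional[Lexicon] = None,
    window_end=None,
    cycle_length: int = 28,
    weight_floor: float = censoring.DEFAULT_WEIGHT_FLOOR,
    min_stratum_size: int = 50,
    io_info: Optional[dict] = None,
) -> dict:
    """Run the full analysis over a query-log frame and return the report."""
    if lexicon is None:
        lexicon = Lexicon.default()
    if window_end is None:
        window_end = pd.Timestamp(log["timestamp"].max()).date() if len(log) else None

    classified = classify_frame(log, lexicon)
    counts = classification_counts(classified)
    timelines = linkage.build_timelines(classified)
    report: dict = {
        "metadata": {
            "n_log_rows": int(len(log)),
            "window_end": str(window_end),
            "cycle_length": cycle_length,
            "weight_floor": weight_floor,
            "n_missed_oc_users": timelines.n_users,
            "n_users_dropped": timelines.n_users_dropped,
            "cohort_hash": _cohort_hash(timelines),
        },
        "classification_counts": counts,
    }
    if io_info:
        report["metadata"].update(io_info)
        if io_info.get("n_rows") and io_info.get("n_skipped_empty", 0) > 0.1 * io_info["n_rows"]:
            report["metadata"]["warning"] = "more than 10% of input rows were skipped"

    if timelines.n_users == 0:
        report["followups"] = {}
        report["rates"] = {}
        report["gestation"] = gestation.gestation_summary(pd.DataFrame())
        logger.warning("no missed_oc users in the log; report has empty cohort sections")
        return report

    report["followups"] = linkage.followup_summary(timelines)

    dist = censoring.estimate_week_distribution(classified)
    report["week_distribution"] = dist.as_dict()
    cohort = build_cohort_table(classified, timelines, dist, window_end)

    overall = censoring.weighted_pregnancy_rate(
        cohort["weight"].to_numpy(), cohort["pregnant"].to_numpy(), floor=weight_floor
    )
    nonplacebo = cohort[~cohort["placebo_mentioned"]]
    nonplacebo_rate = censoring.weighted_pregnancy_rate(
        nonplacebo["weight"].to_numpy(), nonplacebo["pregnant"].to_numpy(), floor=weight_floor
    )
    subgroups = {
        grouping: censoring.subgroup_rates(
            cohort, grouping, floor=weight_floor, min_stratum_size=min_stratum_size
        ).to_dict(orient="records")
        for grouping in censoring.GROUPINGS
    }
    report["rates"] = {
        "overall": overall,
        "non_placebo": nonplacebo_rate,
        "subgroups": subgroups,
    }

    pregnancies = gestation.infer_pregnancies(timelines, cycle_length=cycle_length)
    report["gestation"] = gestation.gestation_summary(pregnancies)

    report["missed_tabulation"] = cohort_stats.tabulate_missed(cohort)

    ages = cohort["age"]
    comparisons = []
    for label in ("abortion", "emergency_contraception"):
        comparisons.append(
            cohort_stats.age_band_ratio(timelines, ages, label, cohort_stats.UNDER_30)
        )
    for label in ("pregnancy_week", "miscarriage"):
        comparisons.append(
            cohort_stats.age_band_ratio(timelines, ages, label, cohort_stats.BAND_30_34)
        )
    report["age_band_comparisons"] = [dataclasses.asdict(c) for c in comparisons]

    pairs = cohort[["age", "n_missed_doses"]].dropna()
    if len(pairs) >= 3:
        rho, p = cohort_stats.age_dose_correlation(pairs["age"], pairs["n_missed_doses"])
        report["age_dose_correlation"] = {"rho": rho, "p_value": p, "n": int(len(pairs))}
    return report


def validate_report(report: dict) -> list[str]:
    """Internal-consistency audit; returns a list of violations."""
    issues = []
    rates = report.get("rates") or {}
    for name in ("overall", "non_placebo"):
        entry = rates.get(name)
        if entry and entry["weighted_rate"] < entry["unweighted_rate"] - 1e-12:
            issues.append(f"{name}: weighted rate below unweighted rate")
    for grouping, rows in (rates.get("subgroups") or {}).items():
        for row in rows:
            if row["n_users"] and row["weighted_rate"] < row["unweighted_rate"] - 1e-12:
                issues.append(f"{grouping}/{row['stratum']}: weighted below unweighted")
    week = report.get("week_distribution")
    if week and abs(sum(week.values()) - 1.0) > 1e-9:
        issues.append("week distribution does not sum to 1")
    return issues


def write_report(report: dict, outdir: str) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    if report.get("followups"):
        pd.DataFrame(report["followups"]).T.to_csv(out / "followup_summary.tsv", sep="\t")
    subgroups = (report.get("rates") or {}).get("subgroups")
    if subgroups:
        frames = [
            pd.DataFrame(rows).assign(grouping=g) for g, rows in subgroups.items()
        ]
        pd.concat(frames).to_csv(out / "subgroup_rates.tsv", sep="\t", index=False)
    if report.get("age_band_comparisons"):
        pd.DataFrame(report["age_band_comparisons"]).to_csv(
            out / "age_band_comparisons.tsv", sep="\t", index=False
        )
    if report.get("week_distribution"):
        pd.Series(report["week_distribution"], name="probability").rename_axis(
            "week"
        ).to_csv(out / "week_distribution.tsv", sep="\t")


def _subgroup_value(report: dict, grouping: str, stratum: str, field: str = "weighted_rate"):
    for row in report["rates"]["subgroups"][grouping]:
        if row["stratum"] == stratum:
            return row[field]
    raise KeyError(f"{grouping}/{stratum} not in report")


def recover(report: dict, truth: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Compare report estimates against the generator's configured truths.

    Raises when the truth sidecar does not come from the same cohort as the
    analysed log (cohort-hash mismatch).  Returns a table of (quantity,
    truth, estimate, se, z, tolerance spec).
    """
    lines = sorted(
        f"{u}:{pd.Timestamp(t).isoformat()}"
        for u, t in zip(truth["user_id"], truth["index_ts"])
    )
    truth_hash = hashlib.sha256("\n".join(lines).encode()).hexdigest()
    if truth_hash != report["metadata"]["cohort_hash"]:
        raise ValueError("run hash mismatch: truth sidecar is not from the analysed log")

    exp = config.expected()
    ges = report["gestation"]
    fol = report["followups"]
    n_rep = ges["n_pregnancy_reporters"]
    n_rec = max(ges["n_recurrent_reporters"], 1)
    n_timed = max(int(round(ges["timed_fraction"] * n_rep)), 1) if n_rep else 1
    ec = fol["emergency_contraception"]
    n_ec = max(ec["n_users_with_followup"], 1)

    def rate_row(name, grouping, stratum, truth_val):
        est = _subgroup_value(report, grouping, stratum)
        n_users = _subgroup_value(report, grouping, stratum, "n_users")
        eff = _subgroup_value(report, grouping, stratum, "effective_n")
        se = np.sqrt(truth_val * (1 - truth_val) * max(n_users, 1)) / max(eff, 1e-9)
        return (name, truth_val, est, se, "se", 3.0)

    np_rate = report["rates"]["non_placebo"]
    se_np = (
        np.sqrt(exp["nonplacebo_rate"] * (1 - exp["nonplacebo_rate"]) * np_rate["n_users"])
        / max(np_rate["effective_n"], 1e-9)
    )
    misc = next(
        c for c in report["age_band_comparisons"] if c["label"] == "miscarriage"
    )
    ratio_se = misc["ratio"] * np.sqrt(
        max(1 - misc["proportion_a"], 0) / max(misc["proportion_a"] * misc["n_a"], 1)
        + max(1 - misc["proportion_b"], 0) / max(misc["proportion_b"] * misc["n_b"], 1)
    )
    rows = [
        ("nonplacebo_rate", exp["nonplacebo_rate"], np_rate["weighted_rate"], se_np, "se", 3.0),
        rate_row("minipill_rate", "pill_type", "progestin_only", exp["minipill_rate"]),
        rate_row("placebo_rate", "placebo", "placebo", exp["placebo_rate"]),
        rate_row("two_plus_rate", "dose_count_2plus", "two_plus", exp["two_plus_rate"]),
        ("ec_median_gap_days", exp["ec_median_gap_days"], ec["median_gap_days"],
         np.nan, "rel", 0.10),
        ("ec_fraction_within_24h", exp["ec_fraction_within_24h"], ec["fraction_within_24h"],
         np.sqrt(exp["ec_fraction_within_24h"] * (1 - exp["ec_fraction_within_24h"]) / n_ec),
         "se", 3.0),
        ("conception_day_mean", exp["conception_day_mean"], ges["conception_day_mean"],
         config.conception_sd / np.sqrt(n_timed), "se", 3.0),
        ("lmp_consistency_days", exp["lmp_consistency_days"],
         ges["lmp_consistency_median_days"], np.nan, "abs", 1.0),
        ("timed_fraction", exp["timed_fraction"], ges["timed_fraction"],
         np.sqrt(exp["timed_fraction"] * (1 - exp["timed_fraction"]) / max(n_rep, 1)),
         "se", 3.0),
        ("miscarriage_age_ratio", exp["miscarriage_age_ratio"], misc["ratio"],
         ratio_se, "se", 3.0),
    ]
    table = pd.DataFrame(
        rows, columns=["quantity", "truth", "estimate", "se", "tol_kind", "tol"]
    )
    table["z"] = (table["estimate"] - table["truth"]) / table["se"]
    within = []
    for _, r in table.iterrows():
        if r["tol_kind"] == "se":
            within.append(abs(r["z"]) <= r["tol"])
        elif r["tol_kind"] == "rel":
            within.append(abs(r["estimate"] - r["truth"]) <= r["tol"] * abs(r["truth"]))
        else:
            within.append(abs(r["estimate"] - r["truth"]) <= r["tol"])
    table["within_tolerance"] = within
    return table
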