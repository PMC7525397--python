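"""Classify the query log and link per-user follow-up timelines.

Reports how many missed-OC users later query about emergency contraception,
abortion, miscarriage or a week of pregnancy; the gap-time medians and
within-24h fractions; and how many follow-ups precede the first
pregnancy-week query.
"""

import pandas as pd

from common import RESULTS, get_run
from ocquery import build_timelines, classify_frame, followup_summary
from ocquery.query_model import classification_counts


def main() -> None:
    _, log, _ = get_run()
    classified = classify_frame(log)
    counts = classification_counts(classified)
    print("classification counts:")
    print(pd.Series(counts).to_string())
    pd.Series(counts, name="count").rename_axis("label").to_csv(
        RESULTS / "classification_counts.tsv", sep="\t"
    )

    timelines = build_timelines(classified)
    summary = pd.DataFrame(followup_summary(timelines)).T
    print(f"\n{timelines.n_users} missed-OC users; follow-up summary:")
    print(summary.round(4).to_string())
    summary.rename_axis("class").to_csv(RESULTS / "followup_summary.tsv", sep="\t")

    ec = summary.loc["emergency_contraception"]
    print(
        f"\nemergency contraception: median gap {ec['median_gap_days']:.1f} days, "
        f"{100 * ec['fraction_within_24h']:.1f}% within 24 h — most users who seek "
        f"it do so days after the missed dose, when it is no longer effective"
    )


if __name__ == "__main__":
    main()
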