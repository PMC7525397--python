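"""Simulate the reference cohort: 50,000 users with a missed-OC query in 2018.

Writes the query log and ground-truth sidecar to scratch/ and a small
scenario summary to results/. The generator encodes the study conditions:
dose-count and pill-type mention shares, stratum pregnancy rates, follow-up
gap-time distributions, and the right-censoring of late pregnancies by the
window end.
"""

import pandas as pd

from common import RESULTS, get_run


def main() -> None:
    config, log, truth = get_run()
    print(f"simulated {len(truth)} users, {len(log)} queries "
          f"({config.window_start}..{config.window_end}, seed {config.seed})")
    summary = pd.Series(
        {
            "n_users": len(truth),
            "n_queries": len(log),
            "n_pregnant_true": int(truth["pregnant"].sum()),
            "n_pregnant_censored": int(truth["censored"].sum()),
            "baseline_rate_solved": round(config.base_rate(), 6),
            "untimed_prior_share_solved": round(config.untimed_prior_share(), 4),
        }
    )
    print(summary.to_string())
    summary.to_csv(RESULTS / "scenario_summary.tsv", sep="\t", header=False)
    print(f"\ncensored pregnancies are unobservable in the log; the weighted "
          f"estimator must correct for them "
          f"({truth['censored'].sum()}/{truth['pregnant'].sum()} censored)")


if __name__ == "__main__":
    main()
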