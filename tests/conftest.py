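import numpy as np
import pandas as pd
import pytest

from ocquery import Lexicon, ScenarioConfig, generate_cohort


@pytest.fixture(scope="session")
def lexicon():
    return Lexicon.default()


@pytest.fixture(scope="session")
def medium_cohort():
    """A mid-sized default-scenario cohort shared across test modules."""
    config = ScenarioConfig(n_users=20_000, seed=7)
    log, truth = generate_cohort(config, include_intent=True)
    return config, log, truth


def make_classified(rows):
    """Build a minimal classified frame from (user, iso_ts, label[, week]) rows."""
    records = []
    for row in rows:
        user, ts, label = row[:3]
        week = row[3] if len(row) > 3 else np.nan
        records.append(
            {
                "user_id": user,
                "timestamp": pd.Timestamp(ts),
                "label": label,
                "pregnancy_week": week,
                "pill_combined": False,
                "pill_progestin": False,
                "placebo_mentioned": False,
                "n_missed_doses": np.nan,
                "age": np.nan,
            }
        )
    df = pd.DataFrame(records)
    df["timestamp"] = df["timestamp"].astype("datetime64[s]")
    return df
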