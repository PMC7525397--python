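"""Query-log reading and writing.

Logs are TSV by default (queries routinely contain commas); CSV with proper
quoting is accepted via the ``.csv`` extension.  Expected columns:
``user_id``, ``timestamp`` (ISO-8601), ``text``, optional ``age`` and
``gender``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["user_id", "timestamp", "text"]


def read_query_log(
    path: str, window_start=None, window_end=None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read a query log; returns (frame, info).

    Rows with empty text after whitespace normalisation are skipped and
    counted; rows outside the observation window (when given) are flagged
    in a boolean ``out_of_window`` column and counted.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"user_id": str, "text": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"query log {path!r} lacks required columns: {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"]).astype("datetime64[s]")
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"], errors="coerce").astype("Int64")
    else:
        df["age"] = pd.array([pd.NA] * len(df), dtype="Int64")
    if "gender" not in df.columns:
        df["gender"] = "unknown"

    blank = df["text"].isna() | (df["text"].str.strip() == "")
    n_skipped = int(blank.sum())
    if n_skipped:
        logger.warning("skipped %d rows with empty query text", n_skipped)
    df = df[~blank].reset_index(drop=True)

    n_out = 0
    if window_start is not None and window_end is not None:
        start = np.datetime64(window_start, "s")
        end = np.datetime64(str(window_end)) + np.timedelta64(1, "D")
        out = (df["timestamp"] < start) | (df["timestamp"].to_numpy() >= end)
        df["out_of_window"] = out
        n_out = int(out.sum())
        if n_out:
            logger.warning("%d rows fall outside the observation window", n_out)
    return df, {"n_rows": len(df), "n_skipped_empty": n_skipped, "n_out_of_window": n_out}
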