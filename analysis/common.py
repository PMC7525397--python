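"""Shared plumbing for the numbered analysis drivers.

Simulates the reference scenario once and caches the query log and
ground-truth sidecar under scratch/ so the drivers can be run in any order.
"""

from pathlib import Path

from ocquery import ScenarioConfig, generate_cohort, read_query_log, read_truth, write_log, write_truth

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

LOG_PATH = SCRATCH / "query_log.tsv"
TRUTH_PATH = SCRATCH / "ground_truth.tsv"


def get_run(n_users: int = 50_000, seed: int = 42):
    """(config, log frame, truth frame) for the reference scenario, cached."""
    config = ScenarioConfig(n_users=n_users, seed=seed)
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    if LOG_PATH.exists() and TRUTH_PATH.exists():
        log, _ = read_query_log(LOG_PATH)
        truth = read_truth(TRUTH_PATH)
        if len(truth) == n_users:
            return config, log, truth
    log, truth = generate_cohort(config)
    write_log(log, str(LOG_PATH))
    write_truth(truth, str(TRUTH_PATH))
    return config, log, truth
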