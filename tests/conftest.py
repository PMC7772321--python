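import json

import pandas as pd
import pytest

from bovitherm.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline on the default synthetic herd (150 cows, seed 0).

    Returns the artifact tables loaded into a dict; shared across tests so
    the herd is simulated and analyzed once per session.
    """
    d = tmp_path_factory.mktemp("default_herd")
    config = PipelineConfig()
    manifest = run_pipeline(config, d)
    out = {"dir": d, "config": config, "manifest": manifest,
           "ledger": json.loads((d / "ledger.json").read_text())}
    dates = {
        "truth.csv": ["episode_onset", "episode_end", "ovulation_time"],
        "episodes.csv": ["onset", "end"],
        "ovulations.csv": ["ovulation_time", "bracket_start", "bracket_end"],
        "exams.csv": ["exam_time"],
        "weather.csv": ["timestamp"],
        "alerts.csv": ["alert_time"],
    }
    for name in ("truth", "episodes", "ovulations", "exams", "weather",
                 "features", "intervals", "alert_summary", "alerts",
                 "group_means"):
        out[name] = pd.read_csv(d / f"{name}.csv",
                                parse_dates=dates.get(f"{name}.csv", False))
    return out
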