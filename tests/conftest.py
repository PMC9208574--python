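import datetime as dt

import numpy as np
import pandas as pd
import pytest

import wardflow as wf


def make_events(rows):
    """Build an event frame from (nurse, room, start_s, end_s) tuples with
    seconds counted from an arbitrary morning anchor."""
    t0 = pd.Timestamp("2020-01-02 08:00:00")
    return pd.DataFrame(
        {
            "nurse_id": [r[0] for r in rows],
            "role": [r[4] if len(r) > 4 else "nurse" for r in rows],
            "unit_id": ["U1"] * len(rows),
            "room_id": [r[1] for r in rows],
            "t_start": [t0 + pd.Timedelta(seconds=r[2]) for r in rows],
            "t_end": [t0 + pd.Timedelta(seconds=r[3]) for r in rows],
        }
    )


@pytest.fixture(scope="session")
def two_stage_sim():
    """A 2-unit ward simulated over a short prepandemic + surge window."""
    stages = [
        wf.StageWindow("prepandemic", dt.date(2020, 1, 1), dt.date(2020, 1, 14)),
        wf.StageWindow("surge1", dt.date(2020, 1, 15), dt.date(2020, 1, 28)),
    ]
    cfg = wf.default_config(
        stages=stages,
        seed=7,
        units={"U1": "covid", "U2": "comparison"},
    )
    return cfg, wf.simulate_ward(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
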