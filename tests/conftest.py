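import numpy as np
import pandas as pd
import pytest

from sdfaces import SimConfig, build_wheel, derive_trials, simulate_experiment


@pytest.fixture(scope="session")
def wheel():
    return build_wheel()


@pytest.fixture(scope="session")
def small_exp1(wheel):
    """Two participants x one 180-trial session, default observer."""
    cfg = SimConfig(experiment=1, n_participants=2, sessions_per_participant=1, seed=7)
    return simulate_experiment(cfg, wheel)


@pytest.fixture(scope="session")
def small_exp2(wheel):
    cfg = SimConfig(experiment=2, n_participants=2, sessions_per_participant=1, seed=7)
    return simulate_experiment(cfg, wheel)


@pytest.fixture(scope="session")
def derived_exp1(small_exp1, wheel):
    return derive_trials(small_exp1, wheel, 1)


def make_trials(rows, experiment=1):
    """Hand-built trial table; rows are dicts with partial columns."""
    defaults = {
        "participant": "p01", "session": 1,
        "isi_s": 1, "delay_s": 1 if experiment == 2 else 0,
        "face1": 0, "face2": 0,
        "postcue": np.nan if experiment == 1 else 2,
        "response": 0, "rt_s": 5.0,
    }
    out = []
    for i, r in enumerate(rows):
        row = defaults | {"trial": i + 1} | r
        out.append(row)
    return pd.DataFrame(out)
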