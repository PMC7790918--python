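import numpy as np
import pandas as pd
import pytest

import clustmsm as cm


@pytest.fixture(scope="session")
def space():
    return cm.illness_death()


@pytest.fixture()
def toy_table():
    """C1: size 1, one 1->2 transition at t=1; C2: size 2, both censored at 2."""
    return pd.DataFrame({
        "cluster": [1, 2, 2],
        "id": [1, 2, 3],
        "entry": [0.0, 0.0, 0.0],
        "exit": [1.0, 2.0, 2.0],
        "from": [1, 1, 1],
        "to": [2, 0, 0],
    })


@pytest.fixture(scope="session")
def sim_data(space):
    """One moderate simulated study used by several inference tests."""
    cfg = cm.SimConfig(n_clusters=200, size_range=(2, 6))
    return cm.simulate_trial(cfg, seed=20_2007), cfg
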