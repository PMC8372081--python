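import numpy as np
import pandas as pd
import pytest

import halfsib as hs


@pytest.fixture(scope="session")
def paper_design():
    """Two populations x 4 blocks x (8 sires x 2 dams): 128 families."""
    return hs.make_design(2, 4, 8, 2, population_labels=["REF", "ASH"])


@pytest.fixture(scope="session")
def one_pop_design():
    return hs.make_design(1, 4, 8, 2, population_labels=["REF"])


@pytest.fixture(scope="session")
def one_env_placements(paper_design):
    """128 families x 6 spatial blocks, single environment (768 rows)."""
    return hs.allocate_field(paper_design, 6, seed=0, environments=["REF"])


@pytest.fixture(scope="session")
def two_env_placements(paper_design):
    units = hs.allocate_embryo_units(paper_design, 2, 3)
    return hs.allocate_field(paper_design, 6, seed=0, units=units)


def exp_survival_frame(n, rate, hr, censor, seed):
    """Two-group exponential survival data (group x in {0,1}, HR on x)."""
    rng = np.random.default_rng(seed)
    x = (np.arange(n) % 2).astype(float)
    t = rng.exponential(1.0 / (rate * np.exp(np.log(hr) * x)))
    stop = np.minimum(t, censor)
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "start": 0.0,
            "stop": stop,
            "event": (t <= censor).astype(int),
            "x": x,
            "blk": rng.integers(0, 12, n),
        }
    )
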