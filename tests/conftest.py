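import numpy as np
import pandas as pd
import pytest

from gaitvar import io, synthetic


@pytest.fixture(scope="session")
def features():
    return io.load_default_features()


@pytest.fixture(scope="session")
def default_cohort():
    """One deterministic default cohort with a few injected implausibles."""
    return synthetic.simulate(synthetic.CohortConfig(seed=11, implausible_rate=0.05))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240730)


def make_runs(rows):
    """Runs table from (dog_id, age_days, run_index, feature_id, value) tuples."""
    return pd.DataFrame(rows, columns=io.RUNS_COLUMNS)
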