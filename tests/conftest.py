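import numpy as np
import pandas as pd
import pytest

from deltami import GenConfig, MissConfig, apply_missingness, simulate_trial


@pytest.fixture(scope="session")
def gen_config():
    return GenConfig()


@pytest.fixture(scope="session")
def trial_table(gen_config):
    """One collapsed complete-data trial at the standard configuration."""
    return simulate_trial(gen_config, 12345)


@pytest.fixture(scope="session")
def masked_table(trial_table):
    """The same trial with 20% MCAR masking of post-baseline weeks."""
    return apply_missingness(trial_table, MissConfig(mcar_p=0.2), 54321)


@pytest.fixture(scope="session")
def small_masked_table():
    """A 40-participant masked trial for fast pipeline tests."""
    table = simulate_trial(GenConfig(n=40), 99)
    return apply_missingness(table, MissConfig(mcar_p=0.25), 7)


def make_manual_table(rows):
    """Build a trial table from (pid, week, age, arm, y, observed) tuples."""
    return pd.DataFrame(rows, columns=["pid", "week", "age", "arm", "y", "observed"])
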