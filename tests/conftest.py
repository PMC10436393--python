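import numpy as np
import pandas as pd
import pytest

from ectoscreen import SimulationConfig, generate_cohort, generate_normal_panel


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def small_panel_config() -> SimulationConfig:
    """Compact panel for fast tissue-specificity checks."""
    return SimulationConfig(seed=11, n_genes=60, n_predominant=10,
                            n_activatable=25, n_prognostic=5)


@pytest.fixture(scope="session")
def panel(small_panel_config):
    return generate_normal_panel(small_panel_config)


@pytest.fixture(scope="session")
def training_cohort(default_config):
    return generate_cohort(default_config, 0)


def make_survival(times, events, start: int = 0) -> pd.DataFrame:
    """Small survival table helper used by hand-oracle tests."""
    idx = [f"s{start + i:03d}" for i in range(len(times))]
    return pd.DataFrame({"dfs_time": np.asarray(times, dtype=float),
                         "dfs_event": np.asarray(events, dtype=int)},
                        index=pd.Index(idx, name="sample_id"))
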