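import numpy as np
import pandas as pd
import pytest

from causalpanel import TimeSeriesPanel, simulate_panel, study_mimic_spec


@pytest.fixture(scope="session")
def mimic_spec():
    return study_mimic_spec()


@pytest.fixture(scope="session")
def mimic_panel(mimic_spec):
    """One seeded study-scale panel, shared across tests that only read it."""
    return simulate_panel(mimic_spec, T=2923, seed=11)


def noise_panel(T: int, n: int, seed: int) -> TimeSeriesPanel:
    """Pure white-noise panel helper."""
    rng = np.random.default_rng(seed)
    return TimeSeriesPanel(
        dates=pd.date_range("2012-01-01", periods=T, freq="D"),
        values=rng.normal(size=(T, n)),
    )
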