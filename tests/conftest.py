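import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lipidrhythm import SimulationConfig, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_config():
    """Desk-scale study: 4 subjects/group, 5 visits, 6 analytes."""
    return SimulationConfig(
        n_subjects_per_group=4,
        sample_times=(18.0, 6.0, 5),
        n_analytes=6,
        fraction_rhythmic_per_group=(0.5, 0.5),
        amplitude=1.5,
        missing_rate=0.05,
        seed=7,
    )


@pytest.fixture
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture
def toy_table():
    """Handmade 2-subject, 4-visit, 1-analyte long table."""
    rows = []
    rng = np.random.default_rng(0)
    for subject, group in [("H01", "healthy"), ("RA01", "RA")]:
        for t in (0.0, 6.0, 12.0, 18.0):
            rows.append((subject, group, t, "CER[N(18)DS(24)]", rng.normal()))
    return pd.DataFrame(rows, columns=["subject", "group", "time_h", "analyte", "value"])
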