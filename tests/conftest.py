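import numpy as np
import pandas as pd
import pytest

from methstage.linmod import build_design
from methstage.simdata import SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sample_sheet(n_controls=10, n_per_stage=10):
    rows = []
    for i in range(n_controls):
        rows.append((f"c{i}", "CONTROL"))
    for stage in ("I", "II", "III", "IV"):
        for i in range(n_per_stage):
            rows.append((f"{stage.lower()}{i}", stage))
    return pd.DataFrame(rows, columns=["sample_id", "parent_stage"])


@pytest.fixture
def sample_sheet():
    return make_sample_sheet()


@pytest.fixture
def stage_design(sample_sheet):
    return build_design(sample_sheet)


@pytest.fixture(scope="session")
def planted_dataset():
    """Small planted cohort shared by integration-style tests."""
    salient = [(i, "II", 3.0) for i in range(5)] + [(i, "IV", -3.0) for i in range(5, 10)]
    agnostic = [(i, 3.0) for i in range(10, 15)]
    cfg = SimConfig(
        n_controls=25,
        n_per_stage=25,
        n_genes=300,
        planted_stage_salient=salient,
        planted_stage_agnostic=agnostic,
        planted_prognostic=[(0, 1.0)],
        missing_rate=0.0,
        seed=202,
    )
    return cfg, simulate_dataset(cfg)
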