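import numpy as np
import pandas as pd
import pytest

from methagesig.data_model import BetaMatrix, SampleSheet, assign_groups
from methagesig.synthetic_data import SimulationConfig, simulate_methylation


@pytest.fixture(scope="session")
def sim():
    """Small synthetic cohort shared across module tests."""
    cfg = SimulationConfig(
        n_probes=2000,
        n_planted_global=50,
        n_planted_distinct=20,
        n_clock_cpgs=50,
        seed=7,
    )
    bm, sheet, ann, truth = simulate_methylation(cfg)
    return cfg, bm, sheet, ann, truth


@pytest.fixture(scope="session")
def sig_result(sim):
    from methagesig.diffmeth import run_signature_pipeline

    _, bm, sheet, _, _ = sim
    return run_signature_pipeline(bm, sheet)


@pytest.fixture
def tiny_beta():
    """3 probes × 4 samples, hand-set values."""
    data = pd.DataFrame(
        [[0.10, 0.20, 0.80, 0.90], [0.50, 0.55, 0.45, 0.40], [0.00, 1.00, 0.30, 0.70]],
        index=pd.Index(["cg1", "cg2", "cg3"], name="probe_id"),
        columns=["s1", "s2", "s3", "s4"],
    )
    return BetaMatrix(data)


@pytest.fixture
def tiny_sheet():
    df = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "age": [30.0, 32.0, 60.0, 70.0],
            "tissue": ["tumour", "tumour", "tumour", "tumour"],
            "subtype": ["TN", "LuminalA", "TN", "LuminalA"],
            "er_status": ["negative", "positive", "negative", "positive"],
            "relapse": ["no", "no", "yes", "no"],
        }
    )
    return assign_groups(SampleSheet(df))
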