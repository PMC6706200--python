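import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from codnet.pipeline import PipelineConfig, run_pipeline
from codnet.synthetic import SimulationConfig, simulate_bundle

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def det_frame(rows):
    """Detection frame from (iso-timestamp, transmitter, receiver) triples."""
    df = pd.DataFrame(rows, columns=["timestamp", "transmitter_id", "receiver_id"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    df["valid"] = True
    return df.sort_values(["transmitter_id", "timestamp"]).reset_index(drop=True)


@pytest.fixture(scope="session")
def bundle8():
    """Reduced-cohort synthetic deployment (8 fish, full study period)."""
    return simulate_bundle(SimulationConfig(seed=1, n_fish=8))


@pytest.fixture(scope="session")
def pipeline_out8(bundle8):
    return run_pipeline(PipelineConfig(seed=1), bundle=bundle8)


@pytest.fixture(scope="session")
def glmm_fixture():
    """Frozen NB-GLMM dataset (15 subjects x 10 weeks, known parameters)."""
    from codnet.synthetic import reference_weekly_sst, simulate_nb_counts

    rng = np.random.default_rng(42)
    y, X, g = simulate_nb_counts(
        rng, reference_weekly_sst(10), n_subjects=15,
        beta0=-1.0, beta_sst=0.25, theta=1.5, sigma_b=0.8,
    )
    return y, X, g
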