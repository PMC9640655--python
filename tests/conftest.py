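import numpy as np
import pytest

from avphenotype import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small multimodal cohort exercising every generator path."""
    cfg = CohortConfig(
        n_scz=8,
        n_mdd=4,
        n_hc=6,
        sessions=2,
        duration_s=20.0,
        feature_sets=("Conversational", "BodyMovement", "LIWC", "Affectiva"),
        table_dims={"LIWC": 12},
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
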