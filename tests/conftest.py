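import numpy as np
import pytest

from gazemetrics.config import ClassifierConfig, CohortConfig, GroupParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_cohort_cfg():
    """Small, quick-to-simulate cohort: short sutures, no failures."""
    return CohortConfig(
        n_novices=3,
        n_experts=3,
        slots=2,
        sutures_per_slot=2,
        expert=GroupParams(14.0, 3.0, 6.0, 0.03),
        novice=GroupParams(20.0, 5.0, 6.0, 0.10),
        p_failed_suture=0.0,
        p_missing_segment=0.0,
        tonic_jitter_sd=0.0,
        away_gap_s=1.0,
        rest_s=7.5,
        seed=7,
    )


@pytest.fixture
def fast_clf_cfg():
    return ClassifierConfig(k_folds=3, repeats=2, seed=3)
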