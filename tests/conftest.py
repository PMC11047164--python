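import numpy as np
import pytest
from hypothesis import settings

import swayn1 as s
from swayn1 import features as F
from swayn1 import pipeline as P

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

COHORT_SEED = 42


@pytest.fixture(scope="session")
def default_params():
    return s.CohortParams(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def default_cohort(default_params):
    """The default 10-subject synthetic cohort (generated once)."""
    return s.generate_cohort(default_params)


@pytest.fixture(scope="session")
def subject0(default_cohort):
    return default_cohort[0]


@pytest.fixture(scope="session")
def cohort_detection(default_cohort):
    """Per-subject detection detail and pooled labeled epochs for the
    default cohort under the default pipeline configuration."""
    cfg = P.PipelineConfig()
    detail, epochs = P.detect_cohort_epochs(default_cohort, cfg)
    return detail, epochs


@pytest.fixture(scope="session")
def feature_table(cohort_detection):
    _, epochs = cohort_detection
    return F.feature_table(epochs)
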