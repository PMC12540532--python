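import numpy as np
import pytest

from liftforce import RunConfig
from liftforce.pipeline import PipelineResult, run_pipeline

#: One fixed cohort seed shared by the slower end-to-end tests.
COHORT_SEED = 7


@pytest.fixture(scope="session")
def default_cohort_result() -> PipelineResult:
    """Full default-condition cohort (29 participants, 81 lifts each),
    simulated, extracted, trimmed and analyzed once per test session."""
    return run_pipeline(RunConfig(seed=COHORT_SEED))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
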