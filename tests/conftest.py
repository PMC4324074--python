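import numpy as np
import pytest

from dynemg import GeneratorParams, StudyConfig, analyze_study, generate_study


@pytest.fixture
def cfg() -> StudyConfig:
    return StudyConfig()


@pytest.fixture(scope="session")
def small_study():
    """3 subjects × 6 cycles: smallest study on which all three tests run."""
    return generate_study(GeneratorParams(n_subjects=3, n_cycles=6, seed=7))


@pytest.fixture(scope="session")
def small_result(small_study):
    return analyze_study(small_study.trials, StudyConfig())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
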