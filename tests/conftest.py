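import numpy as np
import pytest

from mtcooc.synthetic import SynthConfig, generate_cohort, toy_annotation


@pytest.fixture(scope="session")
def default_run():
    """One generated cohort + manifest under the reference conditions."""
    cohort, manifest = generate_cohort(SynthConfig(seed=7))
    return cohort, manifest


@pytest.fixture(scope="session")
def default_annotation():
    return toy_annotation(2000)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
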