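import pytest

from screenseven.cohort import default_config, generate_cohort
from screenseven.scoring import score_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size synthetic cohort under the calibrated default config."""
    return generate_cohort(default_config(n=1245, seed=11))


@pytest.fixture(scope="session")
def default_scores(default_cohort):
    return score_cohort(default_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for I/O and smoke tests."""
    return generate_cohort(default_config(n=40, seed=5))
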