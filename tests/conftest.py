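import pytest

from ocuvegf.config import default_study_config
from ocuvegf.synthetic import SyntheticStudySpec


@pytest.fixture(scope="session")
def config():
    return default_study_config()


@pytest.fixture()
def spec():
    """Default synthetic study spec, deterministic seed."""
    return SyntheticStudySpec(seed=0)
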