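import pytest

from bpscreen.synthetic_data import SyntheticSpec, default_parameter_set


@pytest.fixture(scope="session")
def ps_default():
    """Full synthetic default parameter set (lifetime horizon)."""
    return default_parameter_set()


@pytest.fixture(scope="session")
def ps_short():
    """Shorter-horizon set (ages 35-59) for tests that rerun the model often."""
    return default_parameter_set(SyntheticSpec(overrides={"end_age": 60}))


@pytest.fixture()
def ps_fresh():
    """A mutable copy of the default set for tests that modify parameters."""
    return default_parameter_set()
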