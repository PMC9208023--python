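import pytest

from chemneuron import default_spec


@pytest.fixture(scope="session")
def spec2():
    """Small two-channel neuron with the shipped defaults."""
    return default_spec(N=2, m=1)


@pytest.fixture(scope="session")
def spec5():
    """Five-channel neuron as used in the multi-channel learning tasks."""
    return default_spec(N=5, m=1)
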