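import pytest

from oglycomap import load_map, simulate_calibrations


@pytest.fixture(scope="session")
def entries():
    return load_map()


@pytest.fixture(scope="session")
def calibrations():
    """Noise-free amide/C30 calibrations from simulated DP 1-20 ladders."""
    return simulate_calibrations()
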