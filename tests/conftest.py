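import pytest

from ppiflux import default_registry, io


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def ct_condition():
    """Cellobiose-limited C. thermocellum steady state (packaged fixture)."""
    return io.load_fixture("table1_cthermocellum")


@pytest.fixture(scope="session")
def ts_condition():
    """Cellobiose-limited T. saccharolyticum steady state (packaged fixture)."""
    return io.load_fixture("table1_tsaccharolyticum")
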