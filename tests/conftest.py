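import pytest

from xlquant.fixtures import SimulationConfig, simulate, write_bundle


@pytest.fixture(scope="session")
def bundle():
    """Small deterministic simulation shared across tests."""
    return simulate(SimulationConfig(seed=11, n_shared=2))


@pytest.fixture(scope="session")
def bundle_paths(bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    return write_bundle(bundle, out)
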