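import pytest

from utrzga import SimulationConfig, simulate_bundle, write_bundle


@pytest.fixture(scope="session")
def bundle():
    """A 50-gene synthetic universe, genes on both strands."""
    return simulate_bundle(SimulationConfig(seed=42, n_genes=50))


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    write_bundle(bundle, out)
    return out
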