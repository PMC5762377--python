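import pytest

from panelval.synthetic import SimConfig, simulate_blends, simulate_panel


@pytest.fixture(scope="session")
def small_config():
    return SimConfig.preset("small", seed=7)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_panel(small_config)


@pytest.fixture(scope="session")
def blend_sim(small_panel, small_config):
    return simulate_blends(small_panel, small_config, n_runs=2)


@pytest.fixture(scope="session")
def design_config():
    """Design-scale study conditions (901 regions, 78 genes, 4 blends)."""
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def design_panel(design_config):
    return simulate_panel(design_config)
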