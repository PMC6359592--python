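import pytest

from loop3c.simulate import load_preset, make_locus, write_scenario_bundle


@pytest.fixture(scope="session")
def pc3m_scenario():
    return load_preset("pc3m")


@pytest.fixture(scope="session")
def fibroblast_scenario():
    return load_preset("fibroblast")


@pytest.fixture(scope="session")
def pc3m_locus(pc3m_scenario):
    return make_locus(pc3m_scenario)


@pytest.fixture(scope="session")
def fibroblast_locus(fibroblast_scenario):
    return make_locus(fibroblast_scenario)


@pytest.fixture(scope="session")
def pc3m_bundle(tmp_path_factory, pc3m_scenario):
    """Full on-disk input bundle + run config for the pc3m scenario."""
    outdir = tmp_path_factory.mktemp("pc3m_bundle")
    config = write_scenario_bundle(pc3m_scenario, outdir)
    return outdir, config


@pytest.fixture(scope="session")
def fibroblast_bundle(tmp_path_factory, fibroblast_scenario):
    outdir = tmp_path_factory.mktemp("fibroblast_bundle")
    config = write_scenario_bundle(fibroblast_scenario, outdir)
    return outdir, config
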