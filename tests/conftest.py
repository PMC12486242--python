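import pytest

from muflap import synthetic_data as sd


@pytest.fixture(scope="session")
def base_config():
    return sd.SimulationConfig(seed=0, n_events=5)


@pytest.fixture(scope="session")
def base_lysogen(base_config):
    """A default polylysogen: Mu-like + integrase-type prophage."""
    lysogen, annotations, truth = sd.make_lysogen(base_config)
    return lysogen, annotations, truth


@pytest.fixture(scope="session")
def mu_prophage(base_lysogen):
    lysogen, _, _ = base_lysogen
    return next(p for p in lysogen.prophages if p.mechanism == "transposition")


@pytest.fixture(scope="session")
def ss_prophage(base_lysogen):
    lysogen, _, _ = base_lysogen
    return next(p for p in lysogen.prophages if p.mechanism == "site_specific")
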