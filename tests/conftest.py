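import numpy as np
import pytest

from cartrax.fixtures import load_water_elf_model


@pytest.fixture(scope="session")
def water_model():
    return load_water_elf_model()


@pytest.fixture(scope="session")
def ion_xs(water_model):
    from cartrax.ion import IonCrossSections
    return IonCrossSections(water_model)


@pytest.fixture(scope="session")
def electron_xs(water_model):
    from cartrax.inelastic import ElectronInelastic
    return ElectronInelastic(water_model)


@pytest.fixture(scope="session")
def elastic_xs():
    from cartrax.elastic import ElasticCrossSections
    return ElasticCrossSections()


@pytest.fixture(scope="session")
def transport_model(ion_xs, electron_xs, elastic_xs):
    from cartrax.transport import TransportModel
    return TransportModel(ion_xs=ion_xs, electron_xs=electron_xs,
                          elastic_xs=elastic_xs)


@pytest.fixture(scope="session")
def small_track(transport_model):
    """Small fully recorded 1 GeV run shared by transport/scoring tests."""
    from cartrax.transport import SimulationConfig
    cfg = SimulationConfig(t_mevu=1000.0 / 12.0, n_paths=8, multiplier=10,
                           master_seed=2024, record_events=True)
    return transport_model.run(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
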