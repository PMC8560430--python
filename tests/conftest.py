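import numpy as np
import pytest

from graphel.eis_model import preset_parameters, simulate_spectrum


@pytest.fixture(scope="session")
def pet_params():
    return preset_parameters("PET")


@pytest.fixture(scope="session")
def su8_params():
    return preset_parameters("SU-8")


@pytest.fixture(scope="session")
def pet_spectrum(pet_params):
    return simulate_spectrum(pet_params)


@pytest.fixture(params=["PET", "SU-8"])
def substrate_params(request):
    return preset_parameters(request.param)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
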