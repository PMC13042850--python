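import numpy as np
import pytest

from endospec import thinfilm
from endospec.encoding import BayerResponse, SourceSpectrum, build_encoding_set
from endospec.spectra import SpectralGrid


@pytest.fixture(scope="session")
def grid() -> SpectralGrid:
    return SpectralGrid()


@pytest.fixture(scope="session")
def filter_set(grid):
    return thinfilm.encoding_filter_set(grid)


@pytest.fixture(scope="session")
def enc(grid, filter_set):
    return build_encoding_set(
        filter_set,
        BayerResponse.gaussian_model(grid),
        SourceSpectrum.white_led(grid),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
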