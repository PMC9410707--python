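import numpy as np
import pytest

from alphadec.spectra import PowerSpectrum, default_freq_grid
from alphadec.parameterize import aperiodic_model, gaussian_model
from alphadec.synth import GenerativePreset


@pytest.fixture(scope="session")
def grid():
    return default_freq_grid()


@pytest.fixture
def make_spectrum(grid):
    """Build a synthetic log spectrum from (offset, exponent, peaks, noise)."""

    def _make(offset=1.0, exponent=1.5, peaks=(), noise_sd=0.0, seed=0):
        power = aperiodic_model(grid, offset, exponent)
        for center, height, width in peaks:
            power = power + gaussian_model(grid, center, height, width)
        if noise_sd > 0:
            power = power + np.random.default_rng(seed).normal(0, noise_sd,
                                                               grid.size)
        return PowerSpectrum(grid, power, "log")

    return _make


@pytest.fixture(scope="session")
def null_preset():
    """Default preset: no covariate effects, default noise."""
    return GenerativePreset()


@pytest.fixture(scope="session")
def noiseless_preset():
    d = GenerativePreset().to_dict()
    d["noise_sd"] = 0.0
    return GenerativePreset.from_dict(d)
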