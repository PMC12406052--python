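import numpy as np
import pytest

from ksim import (
    CoilProfile,
    SamplingPattern,
    SequenceParams,
    Shot,
    contrast_volume,
    epi_3d,
    make_coil_profiles,
    make_synthetic_phantom,
)


def brute_force_dft(vol: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Independent double-sum DFT oracle: y[m] = sum_r x[r] e^{-2i pi k_m.r}."""
    shape = vol.shape
    grids = np.meshgrid(*[np.arange(n) - n // 2 for n in shape], indexing="ij")
    r = np.stack([g.ravel() for g in grids], axis=1).astype(float)
    out = np.zeros(len(k), dtype=np.complex128)
    flat = vol.ravel()
    for m, km in enumerate(np.atleast_2d(k)):
        out[m] = np.sum(flat * np.exp(-2j * np.pi * (r @ km)))
    return out


@pytest.fixture(scope="session")
def phantom16():
    return make_synthetic_phantom((16, 16, 16), seed=0)


@pytest.fixture(scope="session")
def phantom32():
    return make_synthetic_phantom((32, 32, 32), seed=1)


@pytest.fixture(scope="session")
def sequence():
    return SequenceParams(TR_shot=50.0, TE=25.0, FA=12.0, Tobs=25.0)


@pytest.fixture(scope="session")
def contrast16(phantom16, sequence):
    return contrast_volume(phantom16, sequence.TR_shot, sequence.TE, sequence.FA)


@pytest.fixture(scope="session")
def single_coil16(phantom16):
    return make_coil_profiles(phantom16, L=1)


@pytest.fixture(scope="session")
def epi_pattern16(phantom16):
    return SamplingPattern(shots=epi_3d(phantom16.shape, 25.0), grid_shape=phantom16.shape)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
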