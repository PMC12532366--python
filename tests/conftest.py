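import numpy as np
import pytest

from entsense import SourceParams


@pytest.fixture
def source():
    return SourceParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_density_matrix(rng, mix=None):
    """Random physical two-qubit state: a Ginibre-random mixed state blended
    with white noise by a (possibly random) mixing weight, which stratifies
    the sample over purity."""
    g = rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))
    rho = g @ g.conj().T
    rho /= np.trace(rho).real
    if mix is None:
        mix = rng.uniform()
    return mix * rho + (1.0 - mix) * np.eye(4) / 4.0


def trace_distance(a, b):
    vals = np.linalg.eigvalsh(a - b)
    return 0.5 * np.sum(np.abs(vals))
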