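import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from twohitscan.io_formats import SignatureSet
from twohitscan.synthetic import default_arms

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def arms():
    return default_arms()


@pytest.fixture(scope="session")
def random_signature_set():
    """Three dense synthetic signatures (fixed seed)."""
    rng = np.random.default_rng(20240)
    matrix = rng.dirichlet(np.ones(96) * 0.3, size=3).T
    return SignatureSet(["S1", "S2", "S3"], matrix)


@pytest.fixture(scope="session")
def block_signature_set():
    """Three identifiable signatures with disjoint 32-channel support (fixed
    seed), mirroring the concentrated channel profiles of real SBS signatures;
    mixture recovery error is then dominated by multinomial sampling noise."""
    rng = np.random.default_rng(20241)
    m = np.zeros((96, 3))
    for k in range(3):
        m[k * 32 : (k + 1) * 32, k] = rng.dirichlet(np.ones(32) * 0.5)
    return SignatureSet(["S1", "S2", "S3"], m)


@pytest.fixture(scope="session")
def sparse_signature_set():
    """Two signatures concentrated on disjoint channels with dyadic weights,
    so small integer catalogues can lie exactly in their non-negative cone."""
    m = np.zeros((96, 2))
    m[0, 0], m[1, 0] = 0.5, 0.5
    m[2, 1], m[3, 1] = 0.25, 0.75
    return SignatureSet(["A", "B"], m)
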