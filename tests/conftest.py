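import numpy as np
import pytest

from hdlc import build_ld_block, simulate_ld_ar1


@pytest.fixture(scope="session")
def ar1_block():
    """Moderate AR(1) region reused across tests (deterministic)."""
    return simulate_ld_ar1(50, 0.7)


@pytest.fixture(scope="session")
def ar1_block_200():
    """The M=200, rho=0.9 region used by the simulation-based checks."""
    return simulate_ld_ar1(200, 0.9)


@pytest.fixture()
def random_corr_block():
    """Factory for small random full-rank correlation blocks."""

    def make(M: int, seed: int):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((M, M + 5))
        return build_ld_block(np.corrcoef(A))

    return make
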