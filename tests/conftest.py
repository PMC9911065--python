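import numpy as np
import pytest

from mutcov import ctmc, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def ergodic_q():
    """A well-conditioned generator with all six rates positive."""
    return ctmc.RateMatrix.from_rates([0.5, 0.3, 2.0, 0.6, 0.12, 0.05])


@pytest.fixture(scope="session")
def small_ma_table():
    """A four-group MA phenotype table at reduced size (shared, read-only)."""
    designs = synthetic.default_designs(
        n_ma_lines=(12, 14),
        n_blocks=6,
        plates_per_line=2,
        beta_ma=np.full(6, 0.2),
        delta_background=np.full(6, 0.4),
    )
    return synthetic.simulate_ma_experiment(designs, np.random.default_rng(11))


@pytest.fixture(scope="session")
def random_psd_matrices():
    """A bank of random 6x6 PSD matrices for property checks."""
    rng = np.random.default_rng(5)
    mats = []
    for _ in range(8):
        a = rng.standard_normal((6, 6))
        mats.append(a @ a.T / 6)
    return mats
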