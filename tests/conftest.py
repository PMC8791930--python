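import numpy as np
import pytest

from mitonuclear.mixed_model import KinshipSpectrum
from mitonuclear.simulate import SimConfig, generate_genotypes


@pytest.fixture(scope="session")
def small_cohort():
    """120-subject admixed cohort with family blocks, reused read-only."""
    cfg = SimConfig(n_subjects=120, n_nusnps=40, n_mtsnps=5, seed=20240101)
    return cfg, generate_genotypes(cfg)


@pytest.fixture(scope="session")
def random_kinship():
    """A dense, well-conditioned PSD kinship with unit diagonal (n=30)."""
    rng = np.random.default_rng(7)
    A = rng.standard_normal((30, 60))
    K = A @ A.T
    d = np.sqrt(np.diag(K))
    K = K / np.outer(d, d)
    return K


@pytest.fixture(scope="session")
def random_kinship_spectrum(random_kinship):
    return KinshipSpectrum.from_kinship(random_kinship)
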