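import numpy as np
import pytest

from metakinase.ilmc import TowerArch, TowerParams
from metakinase.synthdata import SyntheticSpec, generate_world


TINY_SPEC = SyntheticSpec(
    n_compounds=400,
    n_head_kinases=3,
    n_tail_kinases=4,
    d_c=16,
    d_p=8,
    latent_rank=4,
    head_per_class=100,
    head_pool_per_kinase=300,
    tail_pool_per_kinase=140,
    tail_test_per_class=40,
    seed=0,
)


@pytest.fixture(scope="session")
def tiny_world():
    """A small but fully structured synthetic benchmark world."""
    return generate_world(TINY_SPEC)


@pytest.fixture
def tiny_arch():
    """A <=50-parameter two-tower model for finite-difference oracles."""
    return TowerArch(d_c=2, d_p=2, hidden=(2,), embedding_dim=2)


@pytest.fixture
def tiny_params(tiny_arch):
    rng = np.random.default_rng(0)
    return TowerParams(tiny_arch, rng.normal(size=tiny_arch.n_params) * 0.5)


@pytest.fixture
def tiny_batch():
    """Row-aligned (Xc, Xp, y) arrays for the tiny architecture."""
    rng = np.random.default_rng(1)
    n = 8
    return (
        rng.normal(size=(n, 2)),
        rng.normal(size=(n, 2)),
        (rng.random(n) < 0.5).astype(float),
    )
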