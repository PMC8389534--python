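import numpy as np
import pytest

from condock import (PartnerPartition, PoolRecipe, generate_pool,
                     make_toy_complex)


@pytest.fixture(scope="session")
def toy():
    """Small two-chain helix complex (12 residues per chain)."""
    return make_toy_complex(12, seed=1)


@pytest.fixture(scope="session")
def charged_toy():
    """Toy complex with a planted Glu/Lys salt bridge across the interface."""
    return make_toy_complex(12, seed=1, charged=True)


@pytest.fixture(scope="session")
def partition():
    return PartnerPartition.of("A", "B")


@pytest.fixture(scope="session")
def small_pool(toy):
    """10-pose pool: 2 planted clusters of 5."""
    recipe = PoolRecipe(base=toy, n_clusters=2, members_per_cluster=(5, 5),
                        intra_spread=0.2, inter_separation=20.0, seed=7)
    records, truth = generate_pool(recipe)
    return records, truth


def numpy_kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Independent Kabsch RMSD: explicit SVD with det correction."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    h = xc.T @ yc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    dd = np.diag([1.0, 1.0, d])
    r = vt.T @ dd @ u.T
    diff = xc @ r.T - yc
    return float(np.sqrt((diff ** 2).sum() / len(x)))
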