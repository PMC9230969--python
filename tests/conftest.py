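import numpy as np
import pytest

from structphylo.structio import StructureModel
from structphylo.synthetic import SimulationParams, simulate_family


@pytest.fixture(scope="session")
def family6():
    """Default six-taxon synthetic family with decoy domains (seed 7)."""
    return simulate_family(SimulationParams(seed=7))


@pytest.fixture(scope="session")
def tm6(family6):
    from structphylo.pairalign import tm_matrix

    models, _ = family6
    return tm_matrix(models)


@pytest.fixture
def toy_model():
    """Small hand-made zig-zag CA trace."""
    rng = np.random.default_rng(11)
    n = 30
    coords = np.cumsum(rng.normal(scale=1.0, size=(n, 3)), axis=0)
    # renormalise steps to 3.8 A so it looks like a CA chain
    for i in range(1, n):
        v = coords[i] - coords[i - 1]
        coords[i] = coords[i - 1] + 3.8 * v / np.linalg.norm(v)
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
    return StructureModel("toy", seq, coords)


def random_rigid(rng):
    """Random proper rotation + translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, [0, 1]] = Q[:, [1, 0]]
    t = rng.normal(scale=20.0, size=3)
    return Q, t
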