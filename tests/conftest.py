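import numpy as np
import pytest

from annealtomo import Geometry, build_system_matrix, make_phantom, project

BINARY_KINDS = ("foam", "tree", "snowflake", "molecule")


@pytest.fixture(scope="session")
def geom8():
    return Geometry(8, 8)


@pytest.fixture(scope="session")
def system8(geom8):
    return build_system_matrix(geom8)


@pytest.fixture(scope="session")
def foam8(geom8):
    phantom = make_phantom("foam", 8, 2, seed=1)
    return phantom, project(phantom, geom8)


def random_problem(rng, n_max=12):
    """Small random (M, y) least-squares instance for enumeration oracles."""
    n = int(rng.integers(2, n_max + 1))
    m = int(rng.integers(2, n + 4))
    M = rng.standard_normal((m, n))
    y = rng.standard_normal(m)
    return M, y


def enumerate_residuals(M, y):
    """Brute-force oracle: ||Mx - y||^2 for every binary x, in lexicographic
    order of the bit-tuples (bit 0 most significant)."""
    n = M.shape[1]
    out = np.empty(1 << n)
    for idx in range(1 << n):
        x = np.array([(idx >> (n - 1 - b)) & 1 for b in range(n)], dtype=float)
        r = M @ x - y
        out[idx] = r @ r
    return out
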