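import logging

import numpy as np
import pytest

from indelrig.fixtures import FixtureSpec, make_polyalanine
from indelrig.rigidity import BodyBarFramework

logging.getLogger("indelrig").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def helix12():
    return make_polyalanine(FixtureSpec(kind="helix", length=12))


@pytest.fixture(scope="session")
def tripeptide():
    return make_polyalanine(FixtureSpec(kind="strand", length=3))


def random_framework(rng: np.random.Generator, max_bodies: int = 8,
                     max_edges: int = 16) -> BodyBarFramework:
    """Random small body-bar multigraph for oracle-equivalence checks."""
    n = int(rng.integers(2, max_bodies + 1))
    fw = BodyBarFramework(bodies=[(i,) for i in range(n)])
    m = int(rng.integers(1, max_edges + 1))
    for _ in range(m):
        u, v = rng.choice(n, size=2, replace=False)
        fw.add_bars(int(u), int(v), int(rng.integers(1, 7)), "covalent-locked")
    return fw


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation matrix."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
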