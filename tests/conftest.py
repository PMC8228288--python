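from pathlib import Path

import numpy as np
import pytest

from snggat import build_adjacency, fixture_seven_node

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def seven_node():
    return fixture_seven_node()


@pytest.fixture(scope="session")
def seven_adjacency(seven_node):
    return build_adjacency(seven_node)


@pytest.fixture(scope="session")
def expected_adjacency():
    return np.loadtxt(DATA / "seven_node_adjacency.txt", dtype=np.int64)


@pytest.fixture(scope="session")
def expected_second_order():
    return np.loadtxt(DATA / "seven_node_second_order.txt", dtype=np.int64)


def random_sign_graph(rng, n, p=0.4):
    """Random signed adjacency: symmetric, diagonal +1, entries in {-1,0,1}."""
    A = np.eye(n, dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                A[i, j] = A[j, i] = rng.choice([-1, 1])
    return A
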