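import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from socialnull import GroupByIndividualMatrix, NodeTable

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_gbi():
    """Three events over three individuals: {A,B}, {A}, {B,C}."""
    return GroupByIndividualMatrix(
        np.array([[1, 1, 0], [1, 0, 0], [0, 1, 1]]),
        ["A", "B", "C"],
        event_time=[1, 1, 2],
    )


@pytest.fixture
def abc_nodes():
    return NodeTable(["A", "B", "C"], {"sex": np.array(["F", "M", "F"], dtype=object)})


def random_gbi(rng, n_max=10, k_max=50, with_metadata=False):
    """A random valid GBI (every event non-empty), for oracles and round trips."""
    n = int(rng.integers(2, n_max + 1))
    k = int(rng.integers(1, k_max + 1))
    m = (rng.random((k, n)) < 0.4).astype(np.int8)
    empty = m.sum(axis=1) == 0
    for row in np.nonzero(empty)[0]:
        m[row, rng.integers(0, n)] = 1
    ids = [f"id{j}" for j in range(n)]
    if with_metadata:
        return GroupByIndividualMatrix(
            m,
            ids,
            event_time=rng.integers(0, 4, k),
            event_day=rng.integers(1, 3, k),
            event_location=np.array(
                [["north", "south"][v] for v in rng.integers(0, 2, k)], dtype=object
            ),
        )
    return GroupByIndividualMatrix(m, ids)
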