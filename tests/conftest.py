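import numpy as np
import pytest

from phnet.connectivity import DistanceMatrix

# Worked 4-ROI example used across the persistence and graph-metric tests:
# d(A,B)=0.1 d(B,C)=0.3 d(A,C)=0.4 d(C,D)=0.5 d(B,D)=0.8 d(A,D)=0.9
FOUR_NODE = np.array(
    [
        [0.0, 0.1, 0.4, 0.9],
        [0.1, 0.0, 0.3, 0.8],
        [0.4, 0.3, 0.0, 0.5],
        [0.9, 0.8, 0.5, 0.0],
    ]
)


@pytest.fixture
def four_node_dist() -> DistanceMatrix:
    return DistanceMatrix(d=FOUR_NODE.copy(), roi_names=list("ABCD"))


def random_distance(rng: np.random.Generator, n: int, max_d: float = 1.0) -> DistanceMatrix:
    """Random symmetric dissimilarity with zero diagonal, entries in (0, max_d]."""
    m = rng.uniform(0.01, max_d, size=(n, n))
    d = np.triu(m, 1)
    d = d + d.T
    return DistanceMatrix(d=d, roi_names=[f"r{i}" for i in range(n)])
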