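import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gridmem import GridSpec, NetworkParams, build_saturated_matrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def printed_matrix() -> np.ndarray:
    """The worked 4x4 saturated matrix (rows 1110/1101/1011/0111).

    Block orientations [identity, reversed]; its storable 2-sparse patterns
    are {0,1}, {0,2}, {1,3}, {2,3}.
    """
    spec = GridSpec(NetworkParams(4, 2), perms=((0, 1), (1, 0)))
    w = build_saturated_matrix(spec)
    assert w.tolist() == [
        [1, 1, 1, 0],
        [1, 1, 0, 1],
        [1, 0, 1, 1],
        [0, 1, 1, 1],
    ]
    return w


@pytest.fixture
def printed_patterns() -> list:
    return [(0, 1), (0, 2), (1, 3), (2, 3)]
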