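import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from nettop.graph_io import Network


@pytest.fixture
def p3() -> Network:
    return Network.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def triangle() -> Network:
    return Network.from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def k4() -> Network:
    verts = "abcd"
    return Network.from_edges(
        [(u, v) for i, u in enumerate(verts) for v in verts[i + 1 :]]
    )


@pytest.fixture
def star3() -> Network:
    return Network.from_edges([("c", "l1"), ("c", "l2"), ("c", "l3")])


@pytest.fixture
def triangle_pendant() -> Network:
    return Network.from_edges([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
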