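import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from trophicsw.net_io import TrophicNetwork, UndirectedProjection


@pytest.fixture
def triangle() -> UndirectedProjection:
    return UndirectedProjection(nodes=("a", "b", "c"), edges=(("a", "b"), ("a", "c"), ("b", "c")))


@pytest.fixture
def star4() -> UndirectedProjection:
    """Hub h with 4 leaves."""
    return UndirectedProjection(
        nodes=("h", "l1", "l2", "l3", "l4"),
        edges=(("h", "l1"), ("h", "l2"), ("h", "l3"), ("h", "l4")),
    )


@pytest.fixture
def path3() -> UndirectedProjection:
    return UndirectedProjection(nodes=("a", "b", "c"), edges=(("a", "b"), ("b", "c")))


@pytest.fixture
def k5_directed() -> TrophicNetwork:
    nodes = tuple("abcde")
    links = tuple((a, b) for a in nodes for b in nodes if a != b)
    return TrophicNetwork(name="k5", nodes=nodes, links=links)
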