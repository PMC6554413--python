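import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ndseq import UndirectedGraph, fixtures


@pytest.fixture
def triangle():
    return UndirectedGraph(edges=[("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def p3():
    return UndirectedGraph(edges=[("a", "b"), ("b", "c")])


@pytest.fixture
def p4():
    return UndirectedGraph(edges=[("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def p5():
    return fixtures("path", n=5)


@pytest.fixture
def c5():
    return fixtures("cycle", n=5)


@pytest.fixture
def star4():
    return fixtures("star", n=4)


@pytest.fixture
def karate():
    return fixtures("karate")
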