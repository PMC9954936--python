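import numpy as np
import pytest

from treph import VertexFunctionGraph, theorem2_fixture


@pytest.fixture
def t135() -> VertexFunctionGraph:
    """Triangle with vertex values 1, 3, 5 — the worked example used throughout."""
    return VertexFunctionGraph(3, ((0, 1), (1, 2), (0, 2)), (1, 3, 5))


@pytest.fixture
def k2() -> VertexFunctionGraph:
    return VertexFunctionGraph(2, ((0, 1),), (1, 2))


@pytest.fixture
def thm2_pair():
    return theorem2_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
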