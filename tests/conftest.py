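import numpy as np
import pytest

from peptrace.construct import AmpliconContext, ConstructLayout
from peptrace.reads import AnchorSpec
from peptrace.simulate import PositionProbMatrix, generate_clone_library


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def layout():
    return ConstructLayout()


@pytest.fixture
def context():
    return AmpliconContext()


@pytest.fixture
def anchors(layout, context):
    return AnchorSpec.from_layout(layout, context)


@pytest.fixture
def small_pool(rng, layout):
    return generate_clone_library(
        5, layout, include_empty_vector=True, rng=rng
    )


@pytest.fixture
def uniform_probs(layout):
    return PositionProbMatrix.uniform(layout.insert_length)
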