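import pytest

import rescirc as rc


@pytest.fixture
def vimentin():
    return rc.vimentin_model()


@pytest.fixture
def vimentin_circuit(vimentin):
    return rc.rs_to_circuit(vimentin)


@pytest.fixture
def detector():
    return rc.sequence_detector_circuit()


@pytest.fixture
def mealy_circuit():
    return rc.mealy_example_circuit()


# The published truth table of the two-state-bit Mealy example:
# (q1, q2, x1) -> (q1', q2', y1)
MEALY_TABLE = [
    ((0, 0), (0,), (1, 0), (1,)),
    ((0, 0), (1,), (1, 0), (1,)),
    ((0, 1), (0,), (0, 0), (0,)),
    ((0, 1), (1,), (0, 0), (0,)),
    ((1, 0), (0,), (1, 1), (0,)),
    ((1, 0), (1,), (0, 1), (0,)),
    ((1, 1), (0,), (0, 0), (0,)),
    ((1, 1), (1,), (0, 1), (0,)),
]

# The published truth table of the 1101 sequence detector:
# (q2, q1, x) -> (q2', q1', y)
DETECTOR_TABLE = [
    ((0, 0), (0,), (0, 0), (0,)),
    ((0, 0), (1,), (0, 1), (0,)),
    ((0, 1), (0,), (0, 0), (0,)),
    ((0, 1), (1,), (1, 0), (0,)),
    ((1, 0), (0,), (1, 1), (0,)),
    ((1, 0), (1,), (1, 0), (0,)),
    ((1, 1), (0,), (0, 0), (0,)),
    ((1, 1), (1,), (0, 1), (1,)),
]

# The six reactions of the detector's reaction-system translation,
# as (reactants, inhibitors, products) triples.
DETECTOR_REACTIONS = [
    ({"x"}, {"q1", "q2"}, {"q1"}),
    ({"q2"}, {"q1", "x"}, {"q1"}),
    ({"q1", "q2", "x"}, {"d"}, {"q1"}),
    ({"q1", "x"}, {"q2"}, {"q2"}),
    ({"q2"}, {"q1"}, {"q2"}),
    ({"q1", "q2", "x"}, {"d"}, {"y"}),
]
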