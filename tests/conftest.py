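import numpy as np
import pytest

from affcom import (
    EncoderMap,
    OutcomeSpace,
    PIDProblem,
    ProbabilityTable,
    build_decoder,
    induced_joint,
    toy_landscape,
    xor_landscape,
)


@pytest.fixture(scope="session")
def toy():
    return toy_landscape()


@pytest.fixture(scope="session")
def direct_encoders():
    enc = EncoderMap.from_blocks([[1, 4], [2, 3]], 4)
    return enc, enc


@pytest.fixture(scope="session")
def indirect_encoders():
    enc = EncoderMap.from_blocks([[1, 2], [3, 4]], 4)
    return enc, enc


@pytest.fixture(scope="session")
def toy_direct_pair(toy, direct_encoders):
    return build_decoder(toy, *direct_encoders)


@pytest.fixture(scope="session")
def toy_indirect_pair(toy, indirect_encoders):
    return build_decoder(toy, *indirect_encoders)


@pytest.fixture(scope="session")
def xor_table():
    """Joint of two uniform binary inputs and their XOR output."""
    mass = {(x1, x2, x1 ^ x2): 0.25 for x1 in (0, 1) for x2 in (0, 1)}
    space = OutcomeSpace(
        ("X1", "X2", "Y"), {"X1": (0, 1), "X2": (0, 1), "Y": (0, 1)}
    )
    return ProbabilityTable(space, mass)


@pytest.fixture(scope="session")
def xor_problem(xor_table):
    return PIDProblem(xor_table, (("X1",), ("X2",)), ("Y",))


@pytest.fixture(scope="session")
def toy_direct_problem(toy, toy_direct_pair):
    joint = induced_joint(toy, toy_direct_pair)
    return PIDProblem(joint, (("ZB",), ("ZC",)), ("A",))


@pytest.fixture(scope="session")
def toy_indirect_problem(toy, toy_indirect_pair):
    joint = induced_joint(toy, toy_indirect_pair)
    return PIDProblem(joint, (("ZB",), ("ZC",)), ("A",))
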