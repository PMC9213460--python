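from fractions import Fraction

import pytest
from hypothesis import settings

from treeplan import poor, rich

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rich1():
    """Rich environment with p = 1/2, rewards +1/-1."""
    return rich(1)


@pytest.fixture(scope="session")
def poor99():
    """Poor environment with p = 0.01, rewards +1/-(1/99)."""
    return poor(99)


def dyadic(numerator: int, denominator: int = 8) -> Fraction:
    return Fraction(numerator, denominator)
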