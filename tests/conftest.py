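from fractions import Fraction

import pytest

from divindex import builtin_rule
from divindex.fixtures import caterpillar, fig3_tree, fig3_theta_rule, u12_tree


@pytest.fixture(scope="session")
def fig3():
    return fig3_tree()


@pytest.fixture(scope="session")
def u12():
    return u12_tree()


@pytest.fixture(scope="session")
def cat6():
    return caterpillar(6)


@pytest.fixture(scope="session")
def fp():
    return builtin_rule("fp")


@pytest.fixture(scope="session")
def es():
    return builtin_rule("es")


@pytest.fixture(scope="session")
def theta():
    return fig3_theta_rule()


def F(x) -> Fraction:
    return Fraction(x)
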