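import numpy as np
import pytest

from evacgame import (
    GroupEconomics,
    PolicyParams,
    compute_payoff_matrix,
    field_coefficients,
)


@pytest.fixture
def econ():
    """Reference group economics (P=10, C=8, C'=1, D=4, E=2)."""
    return GroupEconomics()


@pytest.fixture
def policy():
    """Base policy profile (alpha=0.5 with grid-midpoint coefficients)."""
    return PolicyParams()


@pytest.fixture
def pm(econ, policy):
    return compute_payoff_matrix(econ, econ, policy)


@pytest.fixture
def coeffs(econ, policy):
    return field_coefficients(econ, econ, policy)


def draw_economics(rng: np.random.Generator) -> GroupEconomics:
    """Random valid economics on the model's natural value scale."""
    C = rng.uniform(0, 10)
    return GroupEconomics(
        P=rng.uniform(0, 20),
        C=C,
        Cprime=C * rng.uniform(0, 1),
        D=rng.uniform(0, 8),
        E=rng.uniform(0, 5),
    )


def draw_policy(rng: np.random.Generator) -> PolicyParams:
    a, b, th, d, eps, eta = rng.uniform(0, 1, size=6)
    return PolicyParams(alpha=a, beta=b, theta=th, delta=d, epsilon=eps, eta=eta)
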