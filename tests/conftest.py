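import numpy as np
import pytest

from markovcea import (
    CohortSpec,
    HealthState,
    TransitionMatrix,
    vietnam_fixture,
)


@pytest.fixture(scope="session")
def fixture_inputs():
    """The bundled Vietnamese knee-OA input set (six regimens)."""
    return vietnam_fixture()


def make_states(n, kinds=None):
    """n states in pathway order, last one death."""
    out = []
    for i in range(n - 1):
        kind = kinds[i] if kinds else ("surgery" if i == n - 2 else "treatment")
        out.append(HealthState(f"s{i}", kind, i))
    out.append(HealthState("death", "death", n - 1))
    return out


def random_chain_matrix(rng, n):
    """A random valid one-way chain: each pre-death state keeps some mass
    and spreads the rest over strictly later states; death absorbing."""
    states = make_states(n)
    probs = np.zeros((n, n))
    for i in range(n - 1):
        w = rng.uniform(0.1, 1.0, size=n - i)  # targets i..n-1
        w /= w.sum()
        probs[i, i:] = w
    probs[n - 1, n - 1] = 1.0
    return TransitionMatrix(states, probs, renormalize=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def simple_cohort(initial="s0", horizon_cycles=10, cycle_length=0.5, mass=1.0):
    return CohortSpec(
        start_age=40.0,
        life_expectancy=40.0 + horizon_cycles * cycle_length,
        initial_state=initial,
        cycle_length=cycle_length,
        cohort_mass=mass,
    )
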