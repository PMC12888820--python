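import numpy as np
import pytest

import tripforage as tf
from tripforage.fixtures import circuit_demo, multi_trip, two_trip


@pytest.fixture(scope="session")
def two_trip_setup():
    cfg = two_trip()
    return cfg.belief(), cfg.params()


@pytest.fixture(scope="session")
def multi_trip_setup():
    cfg = multi_trip()
    return cfg.belief(), cfg.params()


@pytest.fixture(scope="session")
def circuit_demo_setup():
    cfg = circuit_demo()
    return cfg.belief(), cfg.params()


def random_setup(rng, p_range=(-5.0, -0.5)):
    """One valid random (belief, params) draw for property tests.

    Rates, density, decay and horizon are drawn over the ranges a 1D
    forager model plausibly occupies, with mu > R0 and gamma * D <= 1
    enforced so no validation warning fires.
    """
    R0 = rng.uniform(0.05, 1.0)
    RD = -rng.uniform(0.05, 1.0)
    mu = R0 * rng.uniform(2.0, 50.0)
    D = 1000.0
    gamma = rng.uniform(0.0, 1.0 / D)
    p = 10.0 ** rng.uniform(*p_range)
    T = rng.uniform(5000.0, 30000.0)
    return tf.EnvironmentBelief(p, gamma, mu, D), tf.ForagerParams(R0, RD, T)


def random_two_trip(rng, belief, params):
    """A feasible random (dS, dL) pair for the given setup."""
    c = params.trip_time_factor
    hi = min(belief.D, 0.45 * params.T / c)
    dL = rng.uniform(0.2 * hi, hi)
    dS = rng.uniform(0.01 * dL, 0.9 * dL)
    return dS, dL
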