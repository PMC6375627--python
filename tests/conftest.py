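import numpy as np
import pytest

import demosoc as ds


@pytest.fixture(scope="session")
def death_neutral():
    return ds.make_model("death_rate", {"beta": 3, "d": 1, "nu": 0.0}, omega=900, mu=0.006)


@pytest.fixture(scope="session")
def death_altruism():
    return ds.make_model("death_rate", {"beta": 3, "d": 1, "nu": -0.95}, omega=900, mu=0.006)


@pytest.fixture(scope="session")
def death_spite():
    return ds.make_model("death_rate", {"beta": 3, "d": 1, "nu": 0.95}, omega=900, mu=0.006)


@pytest.fixture(scope="session")
def model1():
    """Matched-pair model with constant turnover ratio (b = r + nu x1, m = kappa n)."""
    return ds.make_model("altruism_model1", {"r": 0.6, "kappa": 1.2, "nu": 1.0}, omega=100)


@pytest.fixture(scope="session")
def birth_altruism():
    return ds.make_model(
        "birth_altruism",
        {"beta": 1, "d": 0.5, "nu": 0.75, "kappa1": 0.75, "kappa2": 0.01},
        omega=250,
        mu=0.01,
    )


@pytest.fixture(scope="session")
def birth_spite():
    return ds.make_model(
        "birth_spite",
        {"beta": 8, "d": 1, "nu": 0.75, "a": 0.05, "kappa1": 0.05, "kappa2": 0.2},
        omega=900,
        mu=0.005,
    )


def make_model2(omega, mu, epsilon=0.003):
    return ds.make_model(
        "altruism_model2",
        {"beta": 3, "d": 2.4, "kappa": 1.2, "nu": 1.0},
        omega=omega,
        mu=mu,
        epsilon=epsilon,
    )


def make_model1(omega, mu, epsilon=0.003):
    return ds.make_model(
        "altruism_model1", {"r": 0.6, "kappa": 1.2, "nu": 1.0}, omega=omega, mu=mu, epsilon=epsilon
    )


def bin_masses(dist, edges):
    """Analytic stationary mass per bin, for comparing with occupancy output."""
    masses = np.empty(len(edges) - 1)
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        q = np.linspace(max(lo, dist.p_grid[0]), min(hi, dist.p_grid[-1]), 200)
        masses[i] = np.trapezoid(dist.pdf(q), q)
    return masses / masses.sum()
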