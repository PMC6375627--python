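"""Model library: rate formulas, validity ranges, symmetry and sign conventions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import demosoc as ds
from demosoc.models import DomainError, ModelValidationError


@pytest.mark.parametrize(
    "family, params, x, expected_bm",
    [
        # hand evaluation: b = 3(1 - 2/3) = 1, m = 1 + 0 = 1
        ("death_rate", {"beta": 3, "d": 1, "nu": 0.0}, (1 / 3, 1 / 3), (1.0, 1.0)),
        # nu multiplies x1 = 0, so b = beta regardless of resident density
        ("birth_altruism", {"beta": 1, "d": 0.5, "nu": 0.75, "kappa1": 0.75, "kappa2": 0.01},
         (0.0, 2.0), (1.0, 0.5 + 1.5 + 0.04)),
        # b = r + nu x1 = 0.6 + 0.25, m = kappa n = 1.2 * 0.5
        ("altruism_model1", {"r": 0.6, "kappa": 1.2, "nu": 1.0}, (0.25, 0.25), (0.85, 0.6)),
        # spite: b = 8(1 - 0.75*0.5/(1 + 0.05))
        ("birth_spite", {"beta": 8, "d": 1, "nu": 0.75, "a": 0.05, "kappa1": 0.05, "kappa2": 0.2},
         (0.5, 0.5), (8 * (1 - 0.75 * 0.5 / 1.05), 1 + 0.05 + 0.2)),
    ],
)
def test_rate_formulas_hand_evaluated(family, params, x, expected_bm):
    model = ds.make_model(family, params, omega=100)
    b, m, _ = ds.evaluate_rates(model, np.array(x))
    assert b == pytest.approx(expected_bm[0], rel=1e-12)
    assert m == pytest.approx(expected_bm[1], rel=1e-12)


def test_model2_growth_matches_model1():
    """The matched pair shares per-capita growth b - m at every density."""
    m1 = ds.make_model("altruism_model1", {"r": 0.6, "kappa": 1.2, "nu": 1.0}, omega=100)
    m2 = ds.make_model(
        "altruism_model2", {"beta": 3, "d": 2.4, "kappa": 1.2, "nu": 1.0}, omega=100
    )
    for x in [(0.1, 0.3), (0.5, 0.2), (0.0, 0.7), (0.9, 0.05)]:
        b1, d1, c1 = ds.evaluate_rates(m1, np.array(x))
        b2, d2, c2 = ds.evaluate_rates(m2, np.array(x))
        assert b1 - d1 == pytest.approx(b2 - d2, abs=1e-12)
        assert c1 == pytest.approx(0.6, abs=1e-12)
        assert c2 == pytest.approx(0.6, abs=1e-12)


@pytest.mark.parametrize(
    "family, params, message",
    [
        ("death_rate", {"beta": 3, "d": 1, "nu": 1.5}, "nu in (-1, 1)"),
        ("death_rate", {"beta": 1.9, "d": 1, "nu": 0.95}, "beta > d"),
        ("altruism_model1", {"r": 0.6, "kappa": 1.2, "nu": 1.3}, "kappa > nu > 0"),
        ("altruism_model1", {"r": -0.1, "kappa": 1.2, "nu": 1.0}, "r > 0"),
        ("birth_spite", {"beta": 8, "d": 1, "nu": 1.5, "a": 0.05, "kappa1": 0.05, "kappa2": 0.2},
         "nu in [0, 1]"),
        ("birth_spite", {"beta": 8, "d": 1, "nu": 0.5, "a": 0.0, "kappa1": 0.05, "kappa2": 0.2},
         "a > 0"),
    ],
)
def test_parameter_validity_enforced(family, params, message):
    with pytest.raises(ModelValidationError) as err:
        ds.make_model(family, params, omega=100)
    assert message.split()[0] in str(err.value)


def test_unknown_family_and_bad_plumbing():
    with pytest.raises(ModelValidationError, match="unknown model family"):
        ds.make_model("nonsense", {}, omega=100)
    with pytest.raises(ModelValidationError, match="missing parameters"):
        ds.make_model("death_rate", {"beta": 3, "d": 1}, omega=100)
    with pytest.raises(ModelValidationError, match="unknown parameters"):
        ds.make_model("death_rate", {"beta": 3, "d": 1, "nu": 0, "zeta": 1}, omega=100)
    with pytest.raises(ModelValidationError, match="omega"):
        ds.make_model("death_rate", {"beta": 3, "d": 1, "nu": 0})


def test_negative_density_rejected(death_neutral):
    with pytest.raises(DomainError):
        ds.evaluate_rates(death_neutral, np.array([-0.1, 0.5]))


def test_logistic_birth_clamped_above_capacity(death_neutral):
    b, m, _ = ds.evaluate_rates(death_neutral, np.array([0.8, 0.8]))
    assert b == 0.0
    assert death_neutral.clamp_counts.get("birth", 0) >= 1


@given(
    x1=st.floats(0.01, 2.0),
    x2=st.floats(0.01, 2.0),
    family=st.sampled_from(["death_rate", "birth_altruism", "birth_spite"]),
)
@settings(max_examples=60, deadline=None)
def test_neutral_symmetry_under_type_swap(x1, x2, family):
    """With nu = 0 the two types are demographically interchangeable."""
    params = {
        "death_rate": {"beta": 3, "d": 1, "nu": 0.0},
        "birth_altruism": {"beta": 1, "d": 0.5, "nu": 0.0, "kappa1": 0.75, "kappa2": 0.01},
        "birth_spite": {"beta": 8, "d": 1, "nu": 0.0, "a": 0.05, "kappa1": 0.05, "kappa2": 0.2},
    }[family]
    model = ds.make_model(family, params, omega=100)
    b1, m1, _ = ds.evaluate_rates(model, np.array([x1, x2]), clamp=False)
    b2, m2, _ = ds.evaluate_rates(model, np.array([x2, x1]), clamp=False)
    assert b1 == pytest.approx(b2, rel=1e-12)
    assert m1 == pytest.approx(m2, rel=1e-12)


@pytest.mark.parametrize("nu", [-0.5, 0.5])
def test_death_rate_sign_convention(nu):
    """In the death-rate family, dm/dx1 carries the sign of nu."""
    model = ds.make_model("death_rate", {"beta": 3, "d": 1, "nu": nu}, omega=100)
    h = 1e-6
    for x1, x2 in [(0.2, 0.3), (0.4, 0.1)]:
        _, m_hi, _ = ds.evaluate_rates(model, np.array([x1 + h, x2]))
        _, m_lo, _ = ds.evaluate_rates(model, np.array([x1 - h, x2]))
        assert np.sign((m_hi - m_lo) / (2 * h)) == np.sign(nu)


def test_birth_rate_sign_convention():
    """db/dx1 > 0 for birth altruism, < 0 for birth spite (nu > 0)."""
    alt = ds.make_model(
        "birth_altruism", {"beta": 1, "d": 0.5, "nu": 0.75, "kappa1": 0.75, "kappa2": 0.01},
        omega=100,
    )
    spi = ds.make_model(
        "birth_spite", {"beta": 8, "d": 1, "nu": 0.75, "a": 0.05, "kappa1": 0.05, "kappa2": 0.2},
        omega=100,
    )
    h = 1e-6
    for x1, x2 in [(0.2, 0.3), (0.5, 0.1)]:
        for model, sign in [(alt, 1), (spi, -1)]:
            b_hi, _, _ = ds.evaluate_rates(model, np.array([x1 + h, x2]))
            b_lo, _, _ = ds.evaluate_rates(model, np.array([x1 - h, x2]))
            assert np.sign((b_hi - b_lo) / (2 * h)) == sign


def test_custom_model_reproduces_builtin(model1):
    custom = ds.make_custom_model(
        birth=lambda x: 0.6 + 1.0 * np.asarray(x, float)[0],
        death=lambda x: 1.2 * np.asarray(x, float).sum(axis=0),
        cost=lambda x: np.full(np.asarray(x, float).shape[1:], 0.6),
        omega=100,
    )
    rng = np.random.default_rng(0)
    for _ in range(20):
        x = rng.uniform(0, 1, size=2)
        assert ds.evaluate_rates(custom, x) == pytest.approx(ds.evaluate_rates(model1, x))


def test_scalar_fast_path_matches_vector_rates(birth_spite):
    rng = np.random.default_rng(1)
    for _ in range(20):
        x1, x2 = rng.uniform(0, 2, size=2)
        b, m, c = birth_spite.scalar_rates(x1, x2)
        bv, mv, cv = ds.evaluate_rates(birth_spite, np.array([x1, x2]))
        assert (b, m, c) == pytest.approx((float(bv), float(mv), float(cv)), rel=1e-14)


def test_vectorized_rates_match_loop(birth_altruism):
    """Rate functions broadcast over a (2, R) density block identically."""
    rng = np.random.default_rng(2)
    X = rng.uniform(0, 2, size=(2, 7))
    bB, mB, cB = ds.evaluate_rates(birth_altruism, X)
    for j in range(7):
        b, m, c = ds.evaluate_rates(birth_altruism, X[:, j])
        assert (float(bB[j]), float(mB[j]), float(cB[j])) == pytest.approx((b, m, c))


def test_trait_ladder_generalizes_two_type():
    """A 2-rung ladder must reproduce the two-type death-rate model."""
    ladder = ds.make_trait_ladder(
        "death_rate", [-0.5, 0.0], {"beta": 3, "d": 1}, omega=100
    )
    two = ds.make_model("death_rate", {"beta": 3, "d": 1, "nu": -0.5}, omega=100)
    for x in [(0.1, 0.4), (0.3, 0.3)]:
        bl, ml, _ = ds.evaluate_rates(ladder, np.array(x))
        bt, mt, _ = ds.evaluate_rates(two, np.array(x))
        assert (float(bl), float(ml)) == pytest.approx((float(bt), float(mt)))
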