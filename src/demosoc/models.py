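"""Demographic model library: birth-death-mutation models with social action.

A well-mixed population of ``n_types`` types lives in a habitat of size
``omega`` (individuals per unit density), so a density vector ``x`` corresponds
to integer counts ``N_i = omega * x_i``.  Type ``actor_index`` (type 1 of the
two-type theory, index 0 here) is the *social actor*: its presence alters the
per-capita birth or death rate of every individual indiscriminately.  Because
the action is indiscriminate, all types share the same per-capita birth rate
``b(x)`` and death rate ``m(x)``; only the actor additionally pays the cost
``epsilon * c(x)``.  Mutation flips an individual's type at per-capita rate
``mu``.

Rate functions take densities (not counts) so that all slow-timescale
analytics are free of ``omega``; the simulators do the conversion.

Built-in families (``n = x1 + x2`` is total density):

========================  =====================================================
``death_rate``            b = beta*(1 - n),  m = d*(1 + nu*x1/n)
                          nu < 0: altruism (lowers deaths), nu > 0: spite.
``birth_altruism``        b = beta + nu*x1,  m = d + kappa1*n + kappa2*n**2
``birth_spite``           b = beta*(1 - nu*x1/(n + a)),  same m.
``altruism_model1``       b = r + nu*x1,  m = kappa*n,  c = r
``altruism_model2``       b = beta + nu*x1,  m = d + kappa*n,  c = r = beta - d
========================  =====================================================

The last two form a matched pair: they have identical per-capita growth rates
(hence identical deterministic dynamics and identical frequency drift), but
different population turnover, which is exactly what makes their stochastic
behaviour differ.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "ModelSpec",
    "ModelValidationError",
    "DomainError",
    "MODEL_FAMILIES",
    "MODEL_FORMULAS",
    "make_model",
    "make_custom_model",
    "make_trait_ladder",
    "evaluate_rates",
]

logger = logging.getLogger(__name__)

Array = np.ndarray
RateFunction = Callable[[Array], Array]
ScalarRates = Callable[[float, float], tuple[float, float, float]]


class ModelValidationError(ValueError):
    """Model parameters violate their stated validity range."""


class DomainError(ValueError):
    """Rates evaluated outside the admissible density domain."""


#: family -> human-readable formula string with the parameter constraints.
MODEL_FORMULAS: dict[str, str] = {
    "death_rate": (
        "b = beta*(1 - n), m = d*(1 + nu*x1/n), c = 0"
        "   [nu in (-1, 1), beta > d*(1 + |nu|); nu<0 altruism, nu>0 spite]"
    ),
    "birth_altruism": (
        "b = beta + nu*x1, m = d + kappa1*n + kappa2*n^2, c = 0"
        "   [nu >= 0, beta > d > 0]"
    ),
    "birth_spite": (
        "b = beta*(1 - nu*x1/(n + a)), m = d + kappa1*n + kappa2*n^2, c = 0"
        "   [nu in [0, 1], a > 0, beta > d > 0]"
    ),
    "altruism_model1": (
        "b = r + nu*x1, m = kappa*n, c = r   [r > 0, kappa > nu > 0;"
        " turnover ratio T/n = 2*kappa, constant in p]"
    ),
    "altruism_model2": (
        "b = beta + nu*x1, m = d + kappa*n, c = r = beta - d"
        "   [beta > d > 0, kappa > nu > 0; T/n linearly decreasing in p]"
    ),
    "custom": "user-supplied rate callables",
}

MODEL_FAMILIES = tuple(MODEL_FORMULAS)


@dataclass(frozen=True)
class ModelSpec:
    """A parameterized k-type demographic model.

    ``birth_rate``/``death_rate``/``cost_rate`` map a density vector of shape
    ``(n_types,)`` or ``(n_types, R)`` to the common per-capita rate (scalar or
    shape ``(R,)``).  ``scalar_rates``, when present, is an allocation-free
    two-type fast path ``(x1, x2) -> (b, m, c)`` with clamping applied, used by
    the exact simulator.
    """

    name: str
    n_types: int
    birth_rate: RateFunction
    death_rate: RateFunction
    cost_rate: RateFunction
    epsilon: float
    mu: float
    omega: float
    params: dict
    actor_index: int = 0
    cost_on_birth: bool = False
    scalar_rates: ScalarRates | None = None
    formula: str = ""
    # mutable aggregation of rate-clamp events; not part of model identity
    clamp_counts: dict = field(default_factory=dict, compare=False, repr=False)

    def with_(self, **updates) -> "ModelSpec":
        """Copy with ``omega``/``mu``/``epsilon`` (etc.) replaced.

        Rate closures never capture these three, so replacement is safe.
        """
        import dataclasses

        updates.setdefault("clamp_counts", {})
        return dataclasses.replace(self, **updates)

    def note_clamp(self, which: str) -> None:
        if which not in self.clamp_counts:
            logger.warning(
                "model %r: raw %s rate went negative and was clamped to 0 "
                "(reported once; see clamp_counts for totals)", self.name, which
            )
        self.clamp_counts[which] = self.clamp_counts.get(which, 0) + 1


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ModelValidationError(msg)


def _check_common(omega: float, mu: float, epsilon: float) -> None:
    _require(omega > 0, "habitat size omega must be > 0")
    _require(mu >= 0, "mutation rate mu must be >= 0")
    _require(epsilon >= 0, "cost magnitude epsilon must be >= 0")


def _zero_cost(x: Array) -> Array:
    x = np.asarray(x, dtype=float)
    return np.zeros(x.shape[1:])


def _const_cost(value: float) -> RateFunction:
    def cost(x: Array) -> Array:
        x = np.asarray(x, dtype=float)
        return np.full(x.shape[1:], value)

    return cost


def _actor_fraction(x: Array) -> tuple[Array, Array]:
    """Total density n and actor fraction x1/n (0 where n == 0)."""
    x = np.asarray(x, dtype=float)
    n = x.sum(axis=0)
    safe = np.where(n > 0, n, 1.0)
    frac = np.where(n > 0, x[0] / safe, 0.0)
    return n, frac


# ---------------------------------------------------------------------------
# family builders


def _family_death_rate(beta: float, d: float, nu: float):
    _require(d > 0 and beta > 0, "death_rate family requires beta > 0, d > 0")
    _require(-1.0 < nu < 1.0, "death_rate family requires nu in (-1, 1)")
    _require(
        beta > d * (1.0 + abs(nu)),
        "death_rate family requires beta > d*(1 + |nu|) "
        f"(got beta={beta}, d*(1+|nu|)={d * (1 + abs(nu))})",
    )

    def birth(x: Array) -> Array:
        x = np.asarray(x, dtype=float)
        return beta * (1.0 - x.sum(axis=0))

    def death(x: Array) -> Array:
        _, frac = _actor_fraction(x)
        return d * (1.0 + nu * frac)

    def scalar(x1: float, x2: float) -> tuple[float, float, float]:
        n = x1 + x2
        b = beta * (1.0 - n)
        m = d * (1.0 + nu * x1 / n) if n > 0.0 else d
        return (b if b > 0.0 else 0.0), (m if m > 0.0 else 0.0), 0.0

    return birth, death, _zero_cost, scalar


def _quadratic_death(d: float, kappa1: float, kappa2: float) -> RateFunction:
    def death(x: Array) -> Array:
        x = np.asarray(x, dtype=float)
        n = x.sum(axis=0)
        return d + kappa1 * n + kappa2 * n * n

    return death


def _family_birth_altruism(beta: float, d: float, nu: float, kappa1: float, kappa2: float):
    _require(beta > d > 0, "birth_altruism family requires beta > d > 0")
    _require(nu >= 0, "birth_altruism family requires nu >= 0")
    _require(kappa1 >= 0 and kappa2 >= 0, "kappa1 and kappa2 must be >= 0")
    _require(kappa1 + kappa2 > 0, "need kappa1 > 0 or kappa2 > 0 for density regulation")

    def birth(x: Array) -> Array:
        x = np.asarray(x, dtype=float)
        return beta + nu * x[0]

    def scalar(x1: float, x2: float) -> tuple[float, float, float]:
        n = x1 + x2
        b = beta + nu * x1
        m = d + kappa1 * n + kappa2 * n * n
        return b, m, 0.0

    return birth, _quadratic_death(d, kappa1, kappa2), _zero_cost, scalar


def _family_birth_spite(beta: float, d: float, nu: float, a: float, kappa1: float, kappa2: float):
    _require(beta > d > 0, "birth_spite family requires beta > d > 0")
    _require(0.0 <= nu <= 1.0, "birth_spite family requires nu in [0, 1]")
    _require(a > 0, "birth_spite family requires a > 0")
    _require(kappa1 >= 0 and kappa2 >= 0, "kappa1 and kappa2 must be >= 0")
    _require(kappa1 + kappa2 > 0, "need kappa1 > 0 or kappa2 > 0 for density regulation")

    def birth(x: Array) -> Array:
        x = np.asarray(x, dtype=float)
        n = x.sum(axis=0)
        return beta * (1.0 - nu * x[0] / (n + a))

    def scalar(x1: float, x2: float) -> tuple[float, float, float]:
        n = x1 + x2
        b = beta * (1.0 - nu * x1 / (n + a))
        m = d + kappa1 * n + kappa2 * n * n
        return (b if b > 0.0 else 0.0), m, 0.0

    return birth, _quadratic_death(d, kappa1, kappa2), _zero_cost, scalar


def _family_altruism_model1(r: float, kappa: float, nu: float):
    _require(r > 0, "altruism_model1 requires r > 0")
    _require(kappa > nu > 0, f"altruism_model1 requires kappa > nu > 0 (got kappa={kappa}, nu={nu})")

    def birth(x: Array) -> Array:
        x = np.asarray(x, dtype=float)
        return r + nu * x[0]

    def death(x: Array) -> Array:
        x = np.asarray(x, dtype=float)
        return kappa * x.sum(axis=0)

    def scalar(x1: float, x2: float) -> tuple[float, float, float]:
        return r + nu * x1, kappa * (x1 + x2), r

    return birth, death, _const_cost(r), scalar


def _family_altruism_model2(beta: float, d: float, kappa: float, nu: float):
    _require(beta > d > 0, "altruism_model2 requires beta > d > 0")
    _require(kappa > nu > 0, f"altruism_model2 requires kappa > nu > 0 (got kappa={kappa}, nu={nu})")
    r = beta - d

    def birth(x: Array) -> Array:
        x = np.asarray(x, dtype=float)
        return beta + nu * x[0]

    def death(x: Array) -> Array:
        x = np.asarray(x, dtype=float)
        return d + kappa * x.sum(axis=0)

    def scalar(x1: float, x2: float) -> tuple[float, float, float]:
        return beta + nu * x1, d + kappa * (x1 + x2), r

    return birth, death, _const_cost(r), scalar


_FAMILY_PARAMS: dict[str, tuple[str, ...]] = {
    "death_rate": ("beta", "d", "nu"),
    "birth_altruism": ("beta", "d", "nu", "kappa1", "kappa2"),
    "birth_spite": ("beta", "d", "nu", "a", "kappa1", "kappa2"),
    "altruism_model1": ("r", "kappa", "nu"),
    "altruism_model2": ("beta", "d", "kappa", "nu"),
}

_FAMILY_BUILDERS = {
    "death_rate": _family_death_rate,
    "birth_altruism": _family_birth_altruism,
    "birth_spite": _family_birth_spite,
    "altruism_model1": _family_altruism_model1,
    "altruism_model2": _family_altruism_model2,
}

_COMMON_KEYS = ("omega", "mu", "epsilon")


def make_model(
    name: str,
    params: Mapping[str, float],
    *,
    omega: float | None = None,
    mu: float | None = None,
    epsilon: float | None = None,
    cost_on_birth: bool = False,
) -> ModelSpec:
    """Build a validated two-type model from a named family.

    ``omega``/``mu``/``epsilon`` may be given either as keyword arguments or
    inside ``params``; ``mu`` and ``epsilon`` default to 0 (cost-free, no
    mutation), ``omega`` is required.

    Raises :class:`ModelValidationError` naming the violated constraint for an
    unknown family, missing/extra parameters, or parameters outside the
    family's validity range.
    """
    if name not in _FAMILY_BUILDERS:
        raise ModelValidationError(
            f"unknown model family {name!r}; choose from {sorted(_FAMILY_BUILDERS)} or use make_custom_model"
        )
    params = dict(params)
    common = {}
    for key, kwval in zip(_COMMON_KEYS, (omega, mu, epsilon)):
        inval = params.pop(key, None)
        if kwval is not None and inval is not None and kwval != inval:
            raise ModelValidationError(f"{key} given twice with conflicting values")
        common[key] = kwval if kwval is not None else inval
    if common["omega"] is None:
        raise ModelValidationError("habitat size 'omega' is required")
    common["mu"] = 0.0 if common["mu"] is None else float(common["mu"])
    common["epsilon"] = 0.0 if common["epsilon"] is None else float(common["epsilon"])
    omega_f = float(common["omega"])
    _check_common(omega_f, common["mu"], common["epsilon"])

    wanted = _FAMILY_PARAMS[name]
    missing = [k for k in wanted if k not in params]
    extra = [k for k in params if k not in wanted]
    if missing:
        raise ModelValidationError(f"family {name!r} missing parameters: {missing}")
    if extra:
        raise ModelValidationError(f"family {name!r} got unknown parameters: {extra}")

    args = {k: float(params[k]) for k in wanted}
    birth, death, cost, scalar = _FAMILY_BUILDERS[name](**args)
    spec = ModelSpec(
        name=name,
        n_types=2,
        birth_rate=birth,
        death_rate=death,
        cost_rate=cost,
        epsilon=common["epsilon"],
        mu=common["mu"],
        omega=omega_f,
        params=args,
        actor_index=0,
        cost_on_birth=cost_on_birth,
        scalar_rates=scalar,
        formula=MODEL_FORMULAS[name],
    )
    _sanity_scan(spec)
    return spec


def make_custom_model(
    birth: RateFunction,
    death: RateFunction,
    cost: RateFunction | None = None,
    *,
    omega: float,
    mu: float = 0.0,
    epsilon: float = 0.0,
    n_types: int = 2,
    actor_index: int = 0,
    params: Mapping[str, float] | None = None,
    name: str = "custom",
    cost_on_birth: bool = False,
    scalar_rates: ScalarRates | None = None,
) -> ModelSpec:
    """Wrap user-supplied density-dependent rate callables into a model."""
    _check_common(omega, mu, epsilon)
    spec = ModelSpec(
        name=name,
        n_types=int(n_types),
        birth_rate=birth,
        death_rate=death,
        cost_rate=cost if cost is not None else _zero_cost,
        epsilon=float(epsilon),
        mu=float(mu),
        omega=float(omega),
        params=dict(params or {}),
        actor_index=int(actor_index),
        cost_on_birth=cost_on_birth,
        scalar_rates=scalar_rates,
        formula=MODEL_FORMULAS["custom"],
    )
    _sanity_scan(spec)
    return spec


def make_trait_ladder(
    family: str,
    nus: Sequence[float],
    params: Mapping[str, float],
    *,
    omega: float,
    mu: float = 0.0,
) -> ModelSpec:
    """A k-type 'trait ladder': type i carries social strength ``nus[i]``.

    The social terms generalize additively: the death-rate ladder uses
    ``m = d*(1 + sum_i nu_i x_i / n)``, the birth-rate ladders use
    ``sum_i nu_i x_i`` in place of ``nu*x1``.  Cost-free (epsilon = 0) by
    construction: the ladder is used for cost-free comparisons of trait
    levels.
    """
    nus = np.asarray(list(nus), dtype=float)
    k = nus.size
    _require(k >= 2, "trait ladder needs at least 2 types")
    p = {key: float(params[key]) for key in params}

    if family == "death_rate":
        beta, d = p["beta"], p["d"]
        _require(np.all(np.abs(nus) < 1), "death_rate ladder requires |nu_i| < 1")
        _require(beta > d * (1 + np.max(np.abs(nus))), "requires beta > d*(1+max|nu_i|)")

        def birth(x: Array) -> Array:
            x = np.asarray(x, dtype=float)
            return beta * (1.0 - x.sum(axis=0))

        def death(x: Array) -> Array:
            x = np.asarray(x, dtype=float)
            n = x.sum(axis=0)
            safe = np.where(n > 0, n, 1.0)
            social = np.tensordot(nus, x, axes=(0, 0)) / safe
            return d * (1.0 + np.where(n > 0, social, 0.0))

    elif family == "birth_altruism":
        beta, d = p["beta"], p["d"]
        kappa1, kappa2 = p["kappa1"], p["kappa2"]
        _require(np.all(nus >= 0), "birth_altruism ladder requires nu_i >= 0")

        def birth(x: Array) -> Array:
            x = np.asarray(x, dtype=float)
            return beta + np.tensordot(nus, x, axes=(0, 0))

        death = _quadratic_death(d, kappa1, kappa2)

    elif family == "birth_spite":
        beta, d, a = p["beta"], p["d"], p["a"]
        kappa1, kappa2 = p["kappa1"], p["kappa2"]
        _require(np.all((nus >= 0) & (nus <= 1)), "birth_spite ladder requires nu_i in [0,1]")

        def birth(x: Array) -> Array:
            x = np.asarray(x, dtype=float)
            n = x.sum(axis=0)
            return beta * (1.0 - np.tensordot(nus, x, axes=(0, 0)) / (n + a))

        death = _quadratic_death(d, kappa1, kappa2)

    else:
        raise ModelValidationError(f"no trait-ladder construction for family {family!r}")

    spec = ModelSpec(
        name=f"{family}_ladder",
        n_types=k,
        birth_rate=birth,
        death_rate=death,
        cost_rate=_zero_cost,
        epsilon=0.0,
        mu=float(mu),
        omega=float(omega),
        params={**p, "nus": tuple(float(v) for v in nus)},
        actor_index=0,
        formula=f"{family} ladder over nu = {list(map(float, nus))}",
    )
    _sanity_scan(spec)
    return spec


# ---------------------------------------------------------------------------
# evaluation


def evaluate_rates(model: ModelSpec, x, *, clamp: bool = True):
    """Per-capita (b, m, c) at density vector ``x``.

    With ``clamp=True`` (default) negative raw formula values -- reachable by
    stochastic excursions, e.g. a logistic birth rate at total density above
    carrying capacity -- are clamped to 0 and counted on
    ``model.clamp_counts``.  ``clamp=False`` returns raw values (used by the
    equilibrium root finder, where the sign of b - m matters).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise DomainError("densities must be non-negative")
    b = np.asarray(model.birth_rate(x), dtype=float)
    m = np.asarray(model.death_rate(x), dtype=float)
    c = np.asarray(model.cost_rate(x), dtype=float)
    if not (np.all(np.isfinite(b)) and np.all(np.isfinite(m)) and np.all(np.isfinite(c))):
        raise DomainError(f"model {model.name!r}: non-finite rate at x={x!r}")
    if clamp:
        if np.any(b < 0):
            model.note_clamp("birth")
            b = np.maximum(b, 0.0)
        if np.any(m < 0):
            model.note_clamp("death")
            m = np.maximum(m, 0.0)
    return b, m, c


def _sanity_scan(model: ModelSpec) -> None:
    """Construction-time check: rates finite on a sampling grid of densities."""
    k = model.n_types
    for total in (1e-6, 0.1, 0.5, 1.0, 2.0, 5.0):
        for w in (0.0, 0.25, 0.5, 0.75, 1.0):
            x = np.full(k, total * (1.0 - w) / max(k - 1, 1))
            x[model.actor_index] = total * w
            evaluate_rates(model, x, clamp=False)
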