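"""Headline analyses: optimal social action, reversal scans, mutation sweeps,
and the mutation-fixation chain.

*Optimal social action.*  In a monomorphic actor population (p = 1) the level
of social action ``nu`` minimizing the turnover-to-size ratio ``T(1)/n(1)`` is
stochastically optimal.  For the quadratically regulated birth-rate families
(``m = d + kappa1 n + kappa2 n^2``) closed forms exist with
``theta = sqrt(d / kappa2)``:

* altruism (``b = beta + nu x1``):        ``nu* = kappa1 - |beta - 2 d| / theta``
* spite (``b = beta (1 - nu x1/(n+a))``): ``nu* = (a + theta)(beta - 2 d - kappa1 theta) / (beta theta)``

Both are returned alongside an independent numeric minimization of
``T(1)/n(1)``; for interior optima the two agree to high precision, and when
the closed form lands outside the family's admissible range the numeric
boundary optimum is flagged and is authoritative.

*Reversal scan.*  A selective reversal is a costly social trait (eps > 0)
that is nonetheless favoured by the occupancy criterion.  The scan maps
``mass_above_half`` over an (omega, epsilon) grid, and
:func:`find_reversal_omega` locates the habitat size at which the mass
crosses 1/2 (omega is a continuous scale parameter in the diffusion).

*Mutation-fixation chain.*  With rare mutation the population hops between
monomorphic states; a single trait-j mutant arises in a trait-i population at
rate ``mu_ij N_i`` and fixes with neutral probability ``1/N_i``, so the
transition rate is ``mu_ij`` -- independent of population size.  With
unbiased mutation every monomorphic state is therefore equally occupied,
regardless of the population size each trait sustains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.optimize import minimize_scalar

from .manifold import quasi_equilibrium_density, turnover
from .models import ModelSpec, make_model
from .stationary import favourability, stationary_density

__all__ = [
    "OptimalActionResult",
    "optimal_social_action",
    "reversal_scan",
    "find_reversal_omega",
    "mutation_sweep",
    "monomorphic_transition_rate",
    "trait_chain_stationary",
    "invasion_probability_neutral",
]


@dataclass(frozen=True)
class OptimalActionResult:
    """Optimal social-action strength by closed form and numeric search."""

    family: str
    nu_star_closed: float | None  # None when outside the admissible range
    nu_star_numeric: float
    theta: float                  # sqrt(d / kappa2)
    objective: float              # T(1)/n(1) at the numeric optimum
    boundary_optimum: bool        # numeric optimum pinned at the range edge

    @property
    def nu_star(self) -> float:
        return self.nu_star_closed if self.nu_star_closed is not None else self.nu_star_numeric


def _monomorphic_ratio(family: str, params: dict, nu: float, omega: float) -> float:
    model = make_model(family, dict(params, nu=nu), omega=omega)
    n1 = quasi_equilibrium_density(model, 1.0)
    return turnover(model, 1.0, n1) / n1


def optimal_social_action(
    family: str,
    params: dict,
    *,
    nu_bounds: tuple[float, float] | None = None,
    xatol: float = 1e-10,
) -> OptimalActionResult:
    """Closed-form and numeric minimizer of T/n at p = 1 over nu.

    ``params`` carries the family constants (beta, d, kappa1, kappa2 and, for
    spite, a); requires ``kappa2 > 0`` and ``d > 0`` so theta is defined.
    """
    if family not in ("birth_altruism", "birth_spite"):
        raise ValueError("optimal_social_action applies to the birth-rate families")
    beta, d = float(params["beta"]), float(params["d"])
    kappa1, kappa2 = float(params["kappa1"]), float(params["kappa2"])
    if kappa2 <= 0 or d <= 0:
        raise ValueError("need kappa2 > 0 and d > 0 for theta = sqrt(d/kappa2)")
    theta = math.sqrt(d / kappa2)

    if family == "birth_altruism":
        closed = kappa1 - abs(beta - 2.0 * d) / theta
        lo, hi = nu_bounds if nu_bounds is not None else (1e-9, 50.0)
        admissible = lo <= closed <= hi and closed >= 0
    else:
        a = float(params["a"])
        closed = (a + theta) * (beta - 2.0 * d - kappa1 * theta) / (beta * theta)
        lo, hi = nu_bounds if nu_bounds is not None else (1e-9, 1.0)
        admissible = lo <= closed <= hi

    # omega is irrelevant to the ratio T/n; any value works
    res = minimize_scalar(
        lambda nu: _monomorphic_ratio(family, params, float(nu), omega=1.0),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": xatol},
    )
    nu_num = float(res.x)
    boundary = min(nu_num - lo, hi - nu_num) < 1e-6
    return OptimalActionResult(
        family=family,
        nu_star_closed=float(closed) if admissible else None,
        nu_star_numeric=nu_num,
        theta=theta,
        objective=float(res.fun),
        boundary_optimum=boundary,
    )


def reversal_scan(
    model: ModelSpec,
    omega_values,
    epsilon_values,
    *,
    grid_size: int = 2048,
) -> pd.DataFrame:
    """Favourability over an (omega, epsilon) grid at fixed mu.

    Non-integrable cells are reported with ``integrable=False`` and NaN mass;
    the scan continues.  ``model.mu`` must be positive somewhere a stationary
    distribution is wanted.
    """
    rows = []
    for omega in omega_values:
        for eps in epsilon_values:
            variant = model.with_(omega=float(omega), epsilon=float(eps))
            dist = stationary_density(variant, grid_size=grid_size)
            if not dist.integrable:
                rows.append(
                    {
                        "omega": float(omega),
                        "epsilon": float(eps),
                        "mu": model.mu,
                        "mass_above_half": float("nan"),
                        "favoured": False,
                        "reversal": False,
                        "shape": "non-integrable",
                        "integrable": False,
                    }
                )
                continue
            rep = favourability(dist, variant)
            rows.append(
                {
                    "omega": float(omega),
                    "epsilon": float(eps),
                    "mu": model.mu,
                    "mass_above_half": rep.mass_above_half,
                    "favoured": rep.favoured,
                    "reversal": rep.reversal,
                    "shape": rep.shape,
                    "integrable": True,
                }
            )
    return pd.DataFrame(rows)


def find_reversal_omega(
    model: ModelSpec,
    omega_bracket: tuple[float, float],
    *,
    tol: float = 1e-3,
    grid_size: int = 2048,
) -> float:
    """Bisect on omega for the point where mass_above_half crosses 1/2.

    Omega is treated as a continuous scale parameter of the diffusion.  The
    bracket must straddle the crossing.
    """

    def excess(omega: float) -> float:
        dist = stationary_density(model.with_(omega=float(omega)), grid_size=grid_size)
        if not dist.integrable:
            raise ValueError(f"density not integrable at omega={omega}")
        return float(dist.mass_above_half) - 0.5

    lo, hi = omega_bracket
    f_lo, f_hi = excess(lo), excess(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no reversal boundary in omega bracket {omega_bracket}: "
            f"excess mass {f_lo:.4g} and {f_hi:.4g} have the same sign"
        )
    while hi - lo > tol * max(1.0, abs(hi)):
        mid = 0.5 * (lo + hi)
        f_mid = excess(mid)
        if f_lo * f_mid <= 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    return 0.5 * (lo + hi)


def mutation_sweep(
    model: ModelSpec,
    mu_values,
    *,
    grid_size: int = 2048,
) -> pd.DataFrame:
    """Favourability and distribution shape across mutation rates."""
    rows = []
    for mu in mu_values:
        variant = model.with_(mu=float(mu))
        dist = stationary_density(variant, grid_size=grid_size)
        if not dist.integrable:
            rows.append(
                {
                    "mu": float(mu),
                    "mass_above_half": float("nan"),
                    "shape": "non-integrable",
                    "favoured": False,
                    "integrable": False,
                }
            )
            continue
        rep = favourability(dist, variant)
        rows.append(
            {
                "mu": float(mu),
                "mass_above_half": rep.mass_above_half,
                "shape": rep.shape,
                "favoured": rep.favoured,
                "integrable": True,
            }
        )
    return pd.DataFrame(rows)


def monomorphic_transition_rate(mu_ij: float, N_i: int) -> float:
    """Rate of the monomorphic i -> j transition: mu_ij * N_i * (1/N_i) = mu_ij.

    A mutant lineage arises at rate ``mu_ij N_i`` and fixes with the neutral
    probability ``1/N_i``; the population size cancels exactly.
    """
    if N_i < 1:
        raise ValueError("population size N_i must be >= 1")
    if mu_ij < 0:
        raise ValueError("mutation rate must be >= 0")
    return float(mu_ij) * N_i * (1.0 / N_i)


def trait_chain_stationary(mu_matrix) -> np.ndarray:
    """Stationary distribution of the monomorphic-state Markov chain.

    ``mu_matrix[i, j]`` is the per-capita mutation rate i -> j (diagonal
    ignored).  Since the transition rates equal the mutation rates
    (independent of the per-trait population sizes), a symmetric mutation
    scheme gives the uniform distribution over traits.
    """
    mu = np.asarray(mu_matrix, dtype=float)
    if mu.ndim != 2 or mu.shape[0] != mu.shape[1]:
        raise ValueError("mu_matrix must be square")
    if np.any(mu < 0):
        raise ValueError("mutation rates must be >= 0")
    Q = mu.copy()
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    ns = null_space(Q.T)
    if ns.shape[1] != 1:
        raise ValueError("the trait chain is reducible; stationary distribution not unique")
    pi = ns[:, 0]
    pi = pi / pi.sum()
    if np.any(pi < -1e-12):
        raise ValueError("numerical failure: negative stationary probabilities")
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def invasion_probability_neutral(model: ModelSpec, resident: str = "non_actor") -> float:
    """Neutral invasion probability of a single mutant: 1 / (omega * n(p_res)).

    ``resident='non_actor'`` gives the probability that a single social actor
    invades a resident non-actor population (p_res = 0); ``resident='actor'``
    the reverse.  Valid in the weak-cost limit (eps ~ 0) with mu = 0.
    """
    if resident not in ("actor", "non_actor"):
        raise ValueError("resident must be 'actor' or 'non_actor'")
    p_res = 1.0 if resident == "actor" else 0.0
    n = quasi_equilibrium_density(model, p_res)
    if n <= 0:
        raise ValueError("resident equilibrium density is zero")
    return 1.0 / (model.omega * n)
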