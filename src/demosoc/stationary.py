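"""Stationary distribution of the frequency diffusion and favourability.

For a one-dimensional diffusion with drift ``alpha(p)`` and infinitesimal
variance ``sigma2(p)`` the stationary density (when it exists) is

    pi(p)  propto  (1 / sigma2(p)) * exp( int 2 alpha(q) / sigma2(q) dq ).

With ``alpha = mu (1 - 2p) - eps c p (1 - p)`` and
``sigma2 = p (1 - p) T / (omega n)`` the exponent integrand is

    s(p) = h(p)/p - h(p)/(1-p) - e(p),
    h(p) = 2 mu omega n(p) / T(p),      e(p) = 2 eps c(p) omega n(p) / T(p),

so the density has pure power-law behaviour at the boundaries with exponents
``a0 = h(0) - 1`` at p = 0 and ``a1 = h(1) - 1`` at p = 1.  We exploit this
structure for numerical stability: the singular parts are integrated
analytically, only the regular remainder is integrated numerically (anchored
at p = 1/2 so nothing blows up), and normalization uses Gauss-Jacobi
quadrature with the exact boundary exponents as weights.  The density is
normalizable iff a0 > -1 and a1 > -1, i.e. iff mu > 0; the computed exponents
are reported either way.

Two closed forms are provided for the matched altruism pair:

* ``altruism_model1`` (b = r + nu x1, m = kappa n, c = r):
      pi(p) propto p**(muO/k - 1) (1-p)**(muO/k - 1) exp(-eps r omega p / kappa)
  with muO/k = mu*omega/kappa -- a symmetric Beta tilted by the cost.
* ``altruism_model2`` (b = beta + nu x1, m = d + kappa n, c = r = beta - d):
      pi(p) propto p**(A-1) (1-p)**(B-1) (beta kappa - d nu p)**G,
      A = mu omega r / (beta kappa),  B = mu omega r / (beta kappa - d nu),
      G = r^2 omega eps / (d nu) - A - B - 1.
  The exponents follow from the general formula above with
  n(p) = r/(kappa - nu p) and T(p) = 2 (beta kappa - d nu p)/(kappa - nu p);
  they are certified against the numeric integrator by
  :func:`certify_model2_closed_form`.

The *favourability* verdict is occupancy-based: the social actor is favoured
if the stationary mass above p = 1/2 exceeds 1/2.  A *selective reversal*
is a favoured verdict despite a positive cost (eps > 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.integrate import cumulative_simpson, simpson
from scipy.interpolate import CubicSpline
from scipy.special import roots_jacobi

from .manifold import solve_manifold_grid, quasi_equilibrium_density
from .models import ModelSpec, evaluate_rates

__all__ = [
    "StationaryDistribution",
    "FavourabilityReport",
    "NonIntegrableError",
    "stationary_density",
    "closed_form_model1",
    "closed_form_model2",
    "certify_model2_closed_form",
    "favourability",
]


class NonIntegrableError(ValueError):
    """The stationary density is not normalizable for these mu, omega."""


@dataclass(frozen=True)
class StationaryDistribution:
    """Normalized stationary density on an interior frequency grid."""

    model: ModelSpec
    p_grid: np.ndarray
    log_unnormalized: np.ndarray
    density: np.ndarray | None
    log_normalization: float | None
    integrable: bool
    boundary_exponents: tuple[float, float]  # (a0 at p=0, a1 at p=1)
    mass_above_half: float | None
    _log_g_spline: CubicSpline | None = None

    def pdf(self, p) -> np.ndarray:
        """Evaluate the normalized density at arbitrary interior points."""
        if not self.integrable:
            raise NonIntegrableError(
                f"density not normalizable: boundary exponents {self.boundary_exponents}"
            )
        p = np.asarray(p, dtype=float)
        a0, a1 = self.boundary_exponents
        logpi = a0 * np.log(p) + a1 * np.log1p(-p) + self._log_g_spline(p)
        return np.exp(logpi - self.log_normalization)


@dataclass(frozen=True)
class FavourabilityReport:
    """Occupancy verdict for the social actor."""

    mass_above_half: float
    favoured: bool
    shape: str  # one of {"U", "bell", "boundary-unimodal", "other"}
    reversal: bool
    n_interior_modes: int
    boundary_exponents: tuple[float, float]


def _grid_quantities(model: ModelSpec, p: np.ndarray):
    n = solve_manifold_grid(model, p)
    T = np.empty_like(p)
    c = np.empty_like(p)
    for i, (pi, ni) in enumerate(zip(p, n)):
        x = np.array((pi * ni, (1.0 - pi) * ni))
        b, m, ci = evaluate_rates(model, x)
        T[i] = float(b + m)
        c[i] = float(ci)
    return n, T, c


def _endpoint_h(model: ModelSpec, p: float) -> float:
    n = quasi_equilibrium_density(model, p)
    x = np.array((p * n, (1.0 - p) * n))
    b, m, _ = evaluate_rates(model, x)
    T = float(b + m)
    if T <= 0:
        raise NonIntegrableError(f"turnover T({p}) = {T} is not positive")
    return 2.0 * model.mu * model.omega * n / T


def stationary_density(
    model: ModelSpec, grid_size: int = 2048, *, n_jacobi: int = 200
) -> StationaryDistribution:
    """Stationary density of the frequency diffusion for ``model``.

    ``grid_size`` is the number of uniform subintervals of [0, 1]; the density
    is represented on the interior points.  ``n_jacobi`` controls the order of
    the Gauss-Jacobi rules used for the normalization and the occupancy mass.
    """
    if grid_size % 2:
        grid_size += 1
    M = grid_size
    p = np.arange(1, M) / M
    n, T, c = _grid_quantities(model, p)
    if np.any(T <= 0):
        raise NonIntegrableError("turnover T(p) vanishes in the interior")
    mu_om = 2.0 * model.mu * model.omega
    h = mu_om * n / T
    h0 = _endpoint_h(model, 0.0)
    h1 = _endpoint_h(model, 1.0)
    a0, a1 = h0 - 1.0, h1 - 1.0
    e = 2.0 * model.epsilon * c * model.omega * n / T

    # regular part of 2*alpha/sigma2 after peeling off h0/p - h1/(1-p)
    reg = (h - h0) / p - (h - h1) / (1.0 - p) - e

    # cumulative integral of reg anchored at p = 1/2 (index M//2 - 1)
    mid = M // 2 - 1
    phi = np.empty_like(p)
    phi[mid:] = cumulative_simpson(reg[mid:], x=p[mid:], initial=0.0)
    lower = cumulative_simpson(reg[: mid + 1], x=p[: mid + 1], initial=0.0)
    phi[: mid + 1] = lower - lower[-1]

    # log pi (unnormalized) = a0 ln p + a1 ln(1-p) + ln g,  g = (omega n/T) e^phi
    log_g = np.log(model.omega * n / T) + phi
    log_un = a0 * np.log(p) + a1 * np.log1p(-p) + log_g

    integrable = a0 > -1.0 and a1 > -1.0
    if not integrable:
        return StationaryDistribution(
            model=model,
            p_grid=p,
            log_unnormalized=log_un,
            density=None,
            log_normalization=None,
            integrable=False,
            boundary_exponents=(a0, a1),
            mass_above_half=None,
        )

    spline = CubicSpline(p, log_g)
    # Normalize each half of [0, 1] separately, in log space throughout.
    # A half whose boundary exponent is small (possibly negative) is handled
    # by Gauss-Jacobi with that exponent as the quadrature weight -- exact
    # treatment of the (integrable) boundary singularity.  A large positive
    # exponent means the density vanishes fast at that boundary; there the
    # grid values are regular and composite Simpson applies (the excluded
    # endpoint sliver carries mass < (1/M)^6).
    log_z_below = _log_half_integral(
        p[: mid + 1], log_un[: mid + 1], a_near=a0, a_far=a1, spline=spline,
        side="below", n_jacobi=n_jacobi,
    )
    log_z_above = _log_half_integral(
        p[mid:], log_un[mid:], a_near=a1, a_far=a0, spline=spline,
        side="above", n_jacobi=n_jacobi,
    )
    log_norm = float(np.logaddexp(log_z_below, log_z_above))
    if not np.isfinite(log_norm):
        raise NonIntegrableError(
            f"normalization failed; boundary exponents {(a0, a1)}"
        )
    mass_above = float(np.exp(log_z_above - log_norm))
    density = np.exp(log_un - log_norm)
    return StationaryDistribution(
        model=model,
        p_grid=p,
        log_unnormalized=log_un,
        density=density,
        log_normalization=log_norm,
        integrable=True,
        boundary_exponents=(a0, a1),
        mass_above_half=mass_above,
        _log_g_spline=spline,
    )


def _log_half_integral(
    p_half: np.ndarray,
    log_un_half: np.ndarray,
    *,
    a_near: float,
    a_far: float,
    spline: CubicSpline,
    side: str,
    n_jacobi: int,
) -> float:
    """log of the unnormalized mass on one half of [0, 1].

    ``a_near`` is the boundary exponent at the endpoint this half touches.
    """
    if a_near > 5.0:
        shift = float(np.max(log_un_half))
        z = float(simpson(np.exp(log_un_half - shift), x=p_half))
        if z <= 0:
            raise NonIntegrableError("half-integral vanished; exponents too extreme")
        return shift + math.log(z)
    if side == "below":
        # map [-1,1] -> [0,1/2]; Jacobi weight (1+t)^a0 supplies p^a0
        t, w = roots_jacobi(n_jacobi, 0.0, a_near)
        q = (t + 1.0) / 4.0
        log_terms = np.log(w) + a_far * np.log1p(-q) + spline(q)
    else:
        # map [-1,1] -> [1/2,1]; Jacobi weight (1-t)^a1 supplies (1-p)^a1
        t, w = roots_jacobi(n_jacobi, a_near, 0.0)
        q = (t + 3.0) / 4.0
        log_terms = np.log(w) + a_far * np.log(q) + spline(q)
    shift = float(np.max(log_terms))
    total = float(np.sum(np.exp(log_terms - shift)))
    return shift + math.log(total) + (-a_near - 1.0) * math.log(4.0)


# ---------------------------------------------------------------------------
# closed forms for the matched altruism pair


def closed_form_model1(params: Mapping[str, float], p) -> np.ndarray:
    """Unnormalized stationary density of ``altruism_model1``.

    ``params`` needs r, kappa, mu, omega, epsilon.  Symmetric Beta with both
    exponents ``mu*omega/kappa - 1``, exponentially tilted toward the
    non-actor when epsilon > 0.
    """
    p = np.asarray(p, dtype=float)
    kappa, r = float(params["kappa"]), float(params["r"])
    mu, omega, eps = float(params["mu"]), float(params["omega"]), float(params["epsilon"])
    if kappa <= 0 or omega <= 0:
        raise ValueError("kappa and omega must be positive")
    a = mu * omega / kappa - 1.0
    logpi = a * np.log(p) + a * np.log1p(-p) - eps * r * omega * p / kappa
    return np.exp(logpi - np.max(logpi))


def _model2_exponents(params: Mapping[str, float]) -> tuple[float, float, float, float]:
    beta, d = float(params["beta"]), float(params["d"])
    kappa, nu = float(params["kappa"]), float(params["nu"])
    mu, omega, eps = float(params["mu"]), float(params["omega"]), float(params["epsilon"])
    r = beta - d
    if nu <= 0:
        raise ValueError("the model-2 closed form requires nu > 0 (use model 1 at nu -> 0)")
    if beta * kappa - d * nu <= 0:
        raise ValueError("requires beta*kappa - d*nu > 0 so the factor is positive on [0,1]")
    A = mu * omega * r / (beta * kappa)
    B = mu * omega * r / (beta * kappa - d * nu)
    G = r * r * omega * eps / (d * nu) - A - B - 1.0
    return A, B, G, r


def closed_form_model2(params: Mapping[str, float], p) -> np.ndarray:
    """Unnormalized stationary density of ``altruism_model2``.

    ``params`` needs beta, d, kappa, nu, mu, omega, epsilon.  Returns
    ``p**(A-1) (1-p)**(B-1) (beta*kappa - d*nu*p)**G`` (up to a constant);
    see the module docstring for A, B, G.
    """
    p = np.asarray(p, dtype=float)
    beta, d = float(params["beta"]), float(params["d"])
    kappa, nu = float(params["kappa"]), float(params["nu"])
    A, B, G, _ = _model2_exponents(params)
    logpi = (
        (A - 1.0) * np.log(p)
        + (B - 1.0) * np.log1p(-p)
        + G * np.log(beta * kappa - d * nu * p)
    )
    return np.exp(logpi - np.max(logpi))


def certify_model2_closed_form(
    model: ModelSpec,
    *,
    rtol: float = 1e-4,
    window: tuple[float, float] = (0.01, 0.99),
) -> float:
    """Check the model-2 closed form against the general integrator.

    Compares normalized-ratio profiles (each density divided by its value at
    p = 1/2) on ``window`` and returns the sup relative error; raises
    ``ValueError`` if it exceeds ``rtol``.  This is the authoritative check on
    the closed-form exponents -- the closed form is never trusted silently.
    """
    if model.name != "altruism_model2":
        raise ValueError("certification applies to the altruism_model2 family")
    dist = stationary_density(model)
    lo, hi = window
    sel = (dist.p_grid >= lo) & (dist.p_grid <= hi)
    p = dist.p_grid[sel]
    params = dict(model.params, mu=model.mu, omega=model.omega, epsilon=model.epsilon)
    cf = closed_form_model2(params, p)
    num = dist.pdf(p)
    # both profiles are defined up to a constant; compare after matching at 1/2
    mid = int(np.argmin(np.abs(p - 0.5)))
    rel = np.abs((num / num[mid]) / (cf / cf[mid]) - 1.0)
    err = float(np.max(rel))
    if err > rtol:
        raise ValueError(
            f"model-2 closed form disagrees with the numeric integrator: "
            f"sup relative error {err:.3g} > {rtol:g}"
        )
    return err


# ---------------------------------------------------------------------------
# favourability


def _count_interior_modes(log_density: np.ndarray, tie: float = 1e-10) -> int:
    y = log_density
    up = y[1:-1] > y[:-2] + tie
    down = y[1:-1] > y[2:] + tie
    return int(np.count_nonzero(up & down))


def favourability(dist: StationaryDistribution, model: ModelSpec | None = None) -> FavourabilityReport:
    """Occupancy verdict: favoured iff the mass on (1/2, 1) exceeds 1/2.

    Shape classes: "U" (density diverges at both boundaries), "bell" (single
    interior mode, no boundary divergence), "boundary-unimodal" (mass
    accumulating at/near one boundary, possibly pushed just interior), and
    "other" (flat or multimodal).
    """
    if not dist.integrable:
        raise NonIntegrableError(
            f"cannot assess favourability: density not normalizable "
            f"(boundary exponents {dist.boundary_exponents})"
        )
    model = model if model is not None else dist.model
    a0, a1 = dist.boundary_exponents
    modes = _count_interior_modes(dist.log_unnormalized)
    diverge0, diverge1 = a0 < 0.0, a1 < 0.0
    flat = float(np.ptp(dist.log_unnormalized)) < 1e-8
    if flat:
        shape = "other"
    elif diverge0 and diverge1:
        shape = "U"
    elif diverge0 or diverge1:
        shape = "boundary-unimodal"
    elif modes == 1:
        shape = "bell"
    elif modes == 0:
        shape = "boundary-unimodal"
    else:
        shape = "other"
    mass = float(dist.mass_above_half)
    favoured = mass > 0.5
    return FavourabilityReport(
        mass_above_half=mass,
        favoured=favoured,
        shape=shape,
        reversal=bool(favoured and model.epsilon > 0),
        n_interior_modes=modes,
        boundary_exponents=(a0, a1),
    )
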