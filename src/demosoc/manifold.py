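"""Slow-timescale reduction of a two-type model.

When selection is weak, mutation rare and the habitat large, demographic
(birth/death) dynamics equilibrate fast relative to evolutionary change in the
actor frequency ``p = x1/(x1+x2)``.  The fast dynamics collapse onto the slow
manifold, the stable curve of ecological equilibria ``b = m``, parameterized
by ``p``.  On it:

* ``n(p)``  -- quasi-equilibrium total density (the stable positive root of
  ``b = m`` at fixed actor fraction ``p``);
* ``T(p) = b(p) + m(p) = 2 b(p) = 2 m(p)`` -- population turnover, the total
  per-capita rate of demographic events (also the neutral variance in
  per-capita growth rate);
* the frequency diffusion ``dp = alpha(p) dt + sqrt(sigma2(p)) dW`` with

  ``alpha(p) = mu (1 - 2 p) - epsilon c(p) p (1 - p)``,
  ``sigma2(p) = p (1 - p) T(p) / (omega n(p))``.

The derivative of the turnover-to-size ratio splits into the two competing
effects of the social trait,

  ``d/dp [T/n] = (T/n) * ( -(dn/dp)/n  +  (dT/dp)/T )``,

the first term being the population-*size* effect (larger populations are
buffered against demographic noise), the second the *turnover* effect (slower
turnover means fewer, smaller steps of the frequency random walk).

The quasi-equilibrium is always computed at epsilon = 0: the cost is a
higher-order perturbation of the manifold and enters the reduction only
through the drift ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .models import ModelSpec, evaluate_rates

__all__ = [
    "ManifoldError",
    "SlowManifold",
    "DecompositionResult",
    "quasi_equilibrium_density",
    "solve_manifold_grid",
    "turnover",
    "diffusion_coefficients",
    "turnover_ratio_decomposition",
    "build_manifold",
    "CoefficientTables",
    "coefficient_tables",
]


class ManifoldError(ValueError):
    """No (or no unique) stable ecological equilibrium."""


def _gap_fn(model: ModelSpec, p: float):
    """b - m (raw, unclamped) at total density n with actor fraction p."""
    birth, death = model.birth_rate, model.death_rate

    def gap(n: float) -> float:
        x = np.array((p * n, (1.0 - p) * n))
        return float(birth(x)) - float(death(x))

    return gap


def _stability(gap, root: float) -> float:
    h = 1e-7 * max(1.0, abs(root))
    return (gap(root + h) - gap(root - h)) / (2.0 * h)


def quasi_equilibrium_density(
    model: ModelSpec,
    p: float,
    *,
    bracket: tuple[float, float] | None = None,
    n_max: float | None = None,
    scan_points: int = 256,
) -> float:
    """Stable positive root ``n`` of ``b(x) = m(x)`` with ``x = (pn, (1-p)n)``.

    Roots are located by a sign scan over ``(0, n_max]`` (with ``n_max``
    auto-expanded until ``b < m``) followed by bracketed root refinement;
    stability is decided by the sign of ``d(b - m)/dn``.  Supply an explicit
    ``bracket`` when the model has several stable equilibria.
    """
    if model.n_types != 2:
        raise ManifoldError("the slow-manifold reduction is defined for two-type models")
    if not 0.0 <= p <= 1.0:
        raise ManifoldError(f"frequency p={p} outside [0, 1]")
    gap = _gap_fn(model, p)

    if bracket is not None:
        lo, hi = bracket
        root = brentq(gap, lo, hi, xtol=1e-14, rtol=8.9e-16)
        if _stability(gap, root) >= 0:
            raise ManifoldError(f"root n={root:.6g} in the supplied bracket is not stable")
        return float(root)

    hi = n_max if n_max is not None else 1.0
    if n_max is None:
        while gap(hi) > 0.0:
            hi *= 2.0
            if hi > 1e12:
                raise ManifoldError("no ecological equilibrium: b > m for all scanned densities")
    grid = np.linspace(hi * 1e-9, hi, scan_points)
    vals = np.array([gap(n) for n in grid])
    stable_roots: list[float] = []
    for i in range(scan_points - 1):
        if vals[i] == 0.0:
            continue
        if vals[i] * vals[i + 1] < 0.0 or (vals[i + 1] == 0.0 and vals[i] != 0.0):
            root = brentq(gap, grid[i], grid[i + 1], xtol=1e-14, rtol=8.9e-16)
            if _stability(gap, root) < 0:
                stable_roots.append(float(root))
    if not stable_roots:
        raise ManifoldError(
            f"no ecological equilibrium: b = m has no stable positive root for p={p} "
            f"in (0, {hi:.3g}]"
        )
    if len(stable_roots) > 1:
        raise ManifoldError(
            f"multiple stable equilibria at p={p}: {stable_roots}; pass an explicit bracket"
        )
    return stable_roots[0]


def solve_manifold_grid(model: ModelSpec, p_grid: np.ndarray) -> np.ndarray:
    """n(p) on a grid, walking along the manifold by continuity.

    The first point uses the full scan; subsequent points bracket around the
    previous root, falling back to the scan if the bracket fails (e.g. the
    branch folds).
    """
    p_grid = np.asarray(p_grid, dtype=float)
    out = np.empty_like(p_grid)
    prev: float | None = None
    for i, p in enumerate(p_grid):
        if prev is None:
            prev = quasi_equilibrium_density(model, float(p))
        else:
            gap = _gap_fn(model, float(p))
            lo, hi = 0.5 * prev, 2.0 * prev
            if gap(lo) > 0.0 > gap(hi):
                prev = float(brentq(gap, lo, hi, xtol=1e-14, rtol=8.9e-16))
            else:
                prev = quasi_equilibrium_density(model, float(p))
        out[i] = prev
    return out


def _rates_on_manifold(model: ModelSpec, p: float, n: float):
    x = np.array((p * n, (1.0 - p) * n))
    return evaluate_rates(model, x)


def turnover(model: ModelSpec, p: float, n: float | None = None) -> float:
    """T(p) = b + m on the manifold (equals 2b = 2m there)."""
    if n is None:
        n = quasi_equilibrium_density(model, p)
    b, m, _ = _rates_on_manifold(model, p, n)
    return float(b + m)


def diffusion_coefficients(model: ModelSpec, p: float) -> tuple[float, float]:
    """Drift ``alpha(p)`` and infinitesimal variance ``sigma2(p)`` of Eq.-(1)-type
    frequency diffusion, with the cost evaluated on the manifold."""
    n = quasi_equilibrium_density(model, p)
    b, m, c = _rates_on_manifold(model, p, n)
    T = float(b + m)
    alpha = model.mu * (1.0 - 2.0 * p) - model.epsilon * float(c) * p * (1.0 - p)
    sigma2 = p * (1.0 - p) * T / (model.omega * n)
    return float(alpha), float(sigma2)


@dataclass(frozen=True)
class DecompositionResult:
    """d/dp of T/n and its size/turnover split at a single frequency."""

    total: float          # d/dp [T(p)/n(p)], centred finite difference
    term_size: float      # -(dn/dp)/n   (population-size effect)
    term_turnover: float  # (dT/dp)/T    (turnover effect)
    ratio: float          # T(p)/n(p)
    one_sided: bool = False  # True when p was at a boundary (lower accuracy)


def turnover_ratio_decomposition(
    model: ModelSpec, p: float, *, h: float = 1e-5
) -> DecompositionResult:
    """Finite-difference split of d/dp[T/n] into size and turnover effects."""
    one_sided = False
    lo, hi = p - h, p + h
    if lo < 0.0:
        lo, one_sided = p, True
    if hi > 1.0:
        hi, one_sided = p, True
    if lo == hi:
        raise ManifoldError("degenerate stencil; decrease h")
    n0 = quasi_equilibrium_density(model, p)
    T0 = turnover(model, p, n0)
    n_lo, n_hi = (quasi_equilibrium_density(model, q) for q in (lo, hi))
    T_lo, T_hi = turnover(model, lo, n_lo), turnover(model, hi, n_hi)
    dq = hi - lo
    dn = (n_hi - n_lo) / dq
    dT = (T_hi - T_lo) / dq
    total = (T_hi / n_hi - T_lo / n_lo) / dq
    return DecompositionResult(
        total=float(total),
        term_size=float(-dn / n0),
        term_turnover=float(dT / T0),
        ratio=float(T0 / n0),
        one_sided=one_sided,
    )


@dataclass(frozen=True)
class SlowManifold:
    """Gridded slow-timescale quantities for a two-type model."""

    model: ModelSpec
    p: np.ndarray
    n: np.ndarray
    T: np.ndarray
    cost: np.ndarray
    alpha: np.ndarray
    sigma2: np.ndarray
    ratio: np.ndarray          # T/n
    dratio: np.ndarray         # d/dp (T/n), centred differences on the grid
    term_size: np.ndarray      # -(dn/dp)/n
    term_turnover: np.ndarray  # (dT/dp)/T

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "p": self.p,
                "n": self.n,
                "T": self.T,
                "alpha": self.alpha,
                "sigma2": self.sigma2,
                "ratio": self.ratio,
                "dratio": self.dratio,
                "term_size": self.term_size,
                "term_turnover": self.term_turnover,
            }
        )


def build_manifold(model: ModelSpec, num: int = 401) -> SlowManifold:
    """Tabulate n, T, alpha, sigma2 and the ratio decomposition on [0, 1]."""
    p = np.linspace(0.0, 1.0, num)
    n = solve_manifold_grid(model, p)
    T = np.empty_like(p)
    cost = np.empty_like(p)
    for i, (pi, ni) in enumerate(zip(p, n)):
        b, m, c = _rates_on_manifold(model, float(pi), float(ni))
        T[i] = b + m
        cost[i] = c
    alpha = model.mu * (1.0 - 2.0 * p) - model.epsilon * cost * p * (1.0 - p)
    sigma2 = p * (1.0 - p) * T / (model.omega * n)
    ratio = T / n
    dratio = np.gradient(ratio, p)
    term_size = -np.gradient(n, p) / n
    term_turnover = np.gradient(T, p) / T
    return SlowManifold(
        model=model,
        p=p,
        n=n,
        T=T,
        cost=cost,
        alpha=alpha,
        sigma2=sigma2,
        ratio=ratio,
        dratio=dratio,
        term_size=term_size,
        term_turnover=term_turnover,
    )


@dataclass(frozen=True)
class CoefficientTables:
    """Dense lookup tables of alpha(p) and sigma(p) for fast SDE stepping."""

    p: np.ndarray
    n: np.ndarray
    T: np.ndarray
    alpha: np.ndarray
    sigma: np.ndarray  # sqrt(sigma2)

    def interp(self, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return np.interp(p, self.p, self.alpha), np.interp(p, self.p, self.sigma)


def coefficient_tables(model: ModelSpec, num: int = 4097) -> CoefficientTables:
    mf = build_manifold(model, num=num)
    return CoefficientTables(
        p=mf.p, n=mf.n, T=mf.T, alpha=mf.alpha, sigma=np.sqrt(np.maximum(mf.sigma2, 0.0))
    )
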