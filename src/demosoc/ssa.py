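"""Exact continuous-time simulation of the individual-based process.

Direct-method Gillespie simulation of the birth-death-mutation process that
the frequency diffusion approximates.  At counts ``N = (N_1, ..., N_k)`` and
densities ``x = N/omega`` the event channels are

* birth of type i           at rate ``N_i * b(x)``,
* death of type i           at rate ``N_i * m(x)``,
* extra actor mortality     at rate ``N_a * epsilon * c(x)`` (default cost
  placement; with ``cost_on_birth`` the cost is subtracted from the actor's
  birth rate instead, clamped at 0),
* mutation i -> j (j != i)  at rate ``N_i * mu`` (type conversion of a living
  individual, per ordered pair).

Rates are recomputed after every event (they are density-dependent and
cheap); no tau-leaping.  This simulator is the ground truth the diffusion
reduction is validated against.

Randomness comes from a single ``numpy.random.Generator`` (PCG64) per
realization; ensembles derive per-replicate child generators from the master
seed via ``numpy.random.SeedSequence(seed).spawn``, and the child seed is
recorded with each realization.  Identical seeds give bit-identical event
sequences.

Occupancy histograms weight each visited frequency by its *holding time*
(the stationary density is an occupancy measure; sampling per event would
bias toward high-turnover states).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .models import ModelSpec

__all__ = [
    "Trajectory",
    "TrajectoryEnsemble",
    "FixationEstimate",
    "OccupancyHistogram",
    "SSADeadlockError",
    "simulate_ssa",
    "simulate_ensemble",
    "estimate_fixation_probability",
    "occupancy_histogram",
    "occupancy_ssa",
]

logger = logging.getLogger(__name__)

_BUF = 16384


class SSADeadlockError(RuntimeError):
    """Total event rate reached 0 with no stopping criterion to absorb it."""


@dataclass(frozen=True)
class Trajectory:
    """One realization: event times and per-type counts (possibly thinned)."""

    times: np.ndarray        # (E,)
    counts: np.ndarray       # (E, k) integer counts
    seed: int | None
    stop_reason: str         # "t_max" | "absorption" | "event_cap"
    truncated: bool
    n_events: int
    final_time: float
    final_counts: np.ndarray

    @property
    def frequencies(self) -> np.ndarray:
        tot = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.counts[:, 0] / np.where(tot > 0, tot, 1), np.nan)


@dataclass(frozen=True)
class TrajectoryEnsemble:
    records: list[Trajectory]
    master_seed: int | None

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class FixationEstimate:
    estimate: float  # fraction of replicates fixing the actor
    stderr: float    # binomial standard error
    n_fixed: int
    n_lost: int
    n_extinct: int
    n_excluded: int  # hit the event cap; excluded from the estimate
    replicates: int


@dataclass(frozen=True)
class OccupancyHistogram:
    edges: np.ndarray  # (bins+1,)
    mass: np.ndarray   # (bins,), sums to 1
    total_time: float

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def _child_seeds(master_seed: int | None, n: int) -> list[np.random.SeedSequence]:
    return list(np.random.SeedSequence(master_seed).spawn(n))


def _run_two_type(
    model: ModelSpec,
    N1: int,
    N2: int,
    *,
    t_max: float | None,
    until_absorption: bool,
    event_cap: int | None,
    rng: np.random.Generator,
    record_every: int,
    hist: np.ndarray | None = None,
    burn_in: float = 0.0,
):
    """Tight scalar inner loop for two-type models (the common case)."""
    scalar = model.scalar_rates
    inv_omega = 1.0 / model.omega
    mu = model.mu
    extra_cost = model.epsilon
    cost_on_birth = model.cost_on_birth
    nbins = len(hist) if hist is not None else 0

    t = 0.0
    events = 0
    truncated = False
    stop_reason = "t_max"
    recording = record_every > 0
    times = [0.0] if recording else []
    c1 = [N1] if recording else []
    c2 = [N2] if recording else []

    ebuf = rng.exponential(size=_BUF)
    ubuf = rng.random(size=_BUF)
    bi = 0

    while True:
        if (until_absorption and (N1 == 0 or N2 == 0)) or (N1 == 0 and N2 == 0):
            stop_reason = "absorption"
            break
        b, m, c = scalar(N1 * inv_omega, N2 * inv_omega)
        if cost_on_birth:
            b1 = b - extra_cost * c
            r_b1 = N1 * (b1 if b1 > 0.0 else 0.0)
            r_d1 = N1 * m
        else:
            r_b1 = N1 * b
            r_d1 = N1 * (m + extra_cost * c)
        r_b2 = N2 * b
        r_d2 = N2 * m
        r_m1 = N1 * mu
        r_m2 = N2 * mu
        total = r_b1 + r_b2 + r_d1 + r_d2 + r_m1 + r_m2
        if total <= 0.0:
            if t_max is not None:
                if hist is not None and t_max > burn_in:
                    w = t_max - (t if t > burn_in else burn_in)
                    p = N1 / (N1 + N2)
                    k = int(p * nbins)
                    hist[k if k < nbins else nbins - 1] += w
                t = t_max
                stop_reason = "t_max"
                break
            raise SSADeadlockError(
                f"total event rate is 0 at counts ({N1}, {N2}) with no t_max to run out"
            )
        if bi >= _BUF:
            ebuf = rng.exponential(size=_BUF)
            ubuf = rng.random(size=_BUF)
            bi = 0
        tau = ebuf[bi] / total
        u = ubuf[bi] * total
        bi += 1
        t_next = t + tau
        if t_max is not None and t_next >= t_max:
            if hist is not None and t_max > burn_in:
                w = t_max - (t if t > burn_in else burn_in)
                p = N1 / (N1 + N2)
                k = int(p * nbins)
                hist[k if k < nbins else nbins - 1] += w
            t = t_max
            stop_reason = "t_max"
            break
        if hist is not None and t_next > burn_in:
            w = t_next - (t if t > burn_in else burn_in)
            p = N1 / (N1 + N2)
            k = int(p * nbins)
            hist[k if k < nbins else nbins - 1] += w
        t = t_next
        acc = r_b1
        if u < acc:
            N1 += 1
        else:
            acc += r_b2
            if u < acc:
                N2 += 1
            else:
                acc += r_d1
                if u < acc:
                    N1 -= 1
                else:
                    acc += r_d2
                    if u < acc:
                        N2 -= 1
                    else:
                        acc += r_m1
                        if u < acc:
                            N1 -= 1
                            N2 += 1
                        else:
                            N2 -= 1
                            N1 += 1
        events += 1
        if recording and events % record_every == 0:
            times.append(t)
            c1.append(N1)
            c2.append(N2)
        if event_cap is not None and events >= event_cap:
            stop_reason = "event_cap"
            truncated = True
            break

    if recording and (not times or times[-1] != t):
        times.append(t)
        c1.append(N1)
        c2.append(N2)
    counts = np.column_stack([c1, c2]) if recording else np.empty((0, 2), dtype=np.int64)
    return (
        np.asarray(times, dtype=float),
        counts.astype(np.int64),
        stop_reason,
        truncated,
        events,
        t,
        np.array([N1, N2], dtype=np.int64),
    )


def _run_k_type(
    model: ModelSpec,
    N: np.ndarray,
    *,
    t_max: float | None,
    until_absorption: bool,
    event_cap: int | None,
    rng: np.random.Generator,
    record_every: int,
):
    """Generic k-type loop (numpy per-event; used when no scalar fast path)."""
    k = model.n_types
    N = N.astype(np.int64).copy()
    inv_omega = 1.0 / model.omega
    mu = model.mu
    eps = model.epsilon
    ai = model.actor_index
    others = [j for j in range(k) if j != ai]

    t = 0.0
    events = 0
    truncated = False
    stop_reason = "t_max"
    recording = record_every > 0
    times = [0.0] if recording else []
    counts = [N.copy()] if recording else []

    while True:
        alive = N > 0
        if (until_absorption and alive.sum() <= 1) or not alive.any():
            stop_reason = "absorption"
            break
        x = N * inv_omega
        b = float(np.asarray(model.birth_rate(x)))
        m = float(np.asarray(model.death_rate(x)))
        c = float(np.asarray(model.cost_rate(x)))
        b = max(b, 0.0)
        m = max(m, 0.0)
        birth_rates = N * b
        death_rates = N * m
        if eps > 0.0:
            if model.cost_on_birth:
                birth_rates = birth_rates.astype(float)
                birth_rates[ai] = N[ai] * max(b - eps * c, 0.0)
            else:
                death_rates = death_rates.astype(float)
                death_rates[ai] = N[ai] * (m + eps * c)
        mut_rates = N * mu * (k - 1)  # total out-mutation per type, uniform over targets
        rates = np.concatenate([birth_rates, death_rates, mut_rates]).astype(float)
        total = float(rates.sum())
        if total <= 0.0:
            if t_max is not None:
                t = t_max
                stop_reason = "t_max"
                break
            raise SSADeadlockError(f"total event rate is 0 at counts {N} with no t_max")
        tau = rng.exponential() / total
        if t_max is not None and t + tau >= t_max:
            t = t_max
            stop_reason = "t_max"
            break
        t += tau
        ch = int(rng.choice(3 * k, p=rates / total))
        which, typ = divmod(ch, k)
        if which == 0:
            N[typ] += 1
        elif which == 1:
            N[typ] -= 1
        else:
            targets = [j for j in range(k) if j != typ]
            j = targets[int(rng.integers(len(targets)))]
            N[typ] -= 1
            N[j] += 1
        events += 1
        if recording and events % record_every == 0:
            times.append(t)
            counts.append(N.copy())
        if event_cap is not None and events >= event_cap:
            stop_reason = "event_cap"
            truncated = True
            break

    if recording and (not times or times[-1] != t):
        times.append(t)
        counts.append(N.copy())
    arr = np.asarray(counts, dtype=np.int64) if recording else np.empty((0, k), dtype=np.int64)
    return (
        np.asarray(times, dtype=float),
        arr,
        stop_reason,
        truncated,
        events,
        t,
        N.copy(),
    )


def _validate_start(model: ModelSpec, initial_counts) -> np.ndarray:
    N0 = np.asarray(initial_counts, dtype=np.int64)
    if N0.shape != (model.n_types,):
        raise ValueError(f"initial_counts must have shape ({model.n_types},)")
    if np.any(N0 < 0) or N0.sum() == 0:
        raise ValueError("initial counts must be non-negative and not all zero")
    return N0


def simulate_ssa(
    model: ModelSpec,
    initial_counts,
    *,
    t_max: float | None = None,
    until_absorption: bool = False,
    event_cap: int | None = None,
    seed: int | None = None,
    record_every: int = 1,
) -> Trajectory:
    """One statistically exact realization of the full stochastic process.

    Provide at least one stopping criterion (``t_max``, ``until_absorption``,
    or ``event_cap``).  ``until_absorption`` requires ``mu == 0`` (with
    mutation the process is recurrent and never absorbs).  ``record_every=E``
    stores every E-th event (0 disables recording except the final state).
    """
    N0 = _validate_start(model, initial_counts)
    if t_max is None and not until_absorption and event_cap is None:
        raise ValueError("need a stopping criterion: t_max, until_absorption, or event_cap")
    if until_absorption and model.mu > 0:
        raise ValueError("until_absorption requires mu == 0: with mutation there is no absorption")
    rng = np.random.default_rng(seed)
    if model.n_types == 2 and model.scalar_rates is not None:
        out = _run_two_type(
            model,
            int(N0[0]),
            int(N0[1]),
            t_max=t_max,
            until_absorption=until_absorption,
            event_cap=event_cap,
            rng=rng,
            record_every=record_every,
        )
    else:
        out = _run_k_type(
            model,
            N0,
            t_max=t_max,
            until_absorption=until_absorption,
            event_cap=event_cap,
            rng=rng,
            record_every=record_every,
        )
    times, counts, stop_reason, truncated, events, t_final, n_final = out
    return Trajectory(
        times=times,
        counts=counts,
        seed=seed,
        stop_reason=stop_reason,
        truncated=truncated,
        n_events=events,
        final_time=t_final,
        final_counts=n_final,
    )


def simulate_ensemble(
    model: ModelSpec,
    initial_counts,
    replicates: int,
    *,
    seed: int | None = None,
    **kwargs,
) -> TrajectoryEnsemble:
    """Independent realizations with child seeds split from ``seed``."""
    records = []
    for ss in _child_seeds(seed, replicates):
        child_seed = int(ss.generate_state(1)[0])
        records.append(simulate_ssa(model, initial_counts, seed=child_seed, **kwargs))
    return TrajectoryEnsemble(records=records, master_seed=seed)


def estimate_fixation_probability(
    model: ModelSpec,
    initial_counts,
    replicates: int,
    *,
    seed: int | None = None,
    event_cap: int | None = None,
) -> FixationEstimate:
    """Fraction of replicates in which the social actor sweeps to fixation.

    Runs each replicate to absorption (requires ``mu == 0``).  Replicates
    hitting ``event_cap`` are excluded from the estimate but counted; total
    extinction counts as non-fixation.  The standard error is binomial.
    """
    if model.mu > 0:
        raise ValueError("fixation requires mu == 0 (absorbing boundaries)")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    N0 = _validate_start(model, initial_counts)
    ai = model.actor_index
    if int(N0.sum() - N0[ai]) == 0:
        return FixationEstimate(1.0, 0.0, replicates, 0, 0, 0, replicates)
    n_fixed = n_lost = n_extinct = n_excluded = 0
    for ss in _child_seeds(seed, replicates):
        child_seed = int(ss.generate_state(1)[0])
        traj = simulate_ssa(
            model,
            N0,
            until_absorption=True,
            event_cap=event_cap,
            seed=child_seed,
            record_every=0,
        )
        if traj.truncated:
            n_excluded += 1
            continue
        final = traj.final_counts
        if final.sum() == 0:
            n_extinct += 1
        elif final.sum() == final[ai]:
            n_fixed += 1
        else:
            n_lost += 1
    used = replicates - n_excluded
    if n_excluded > 0.01 * replicates:
        warnings.warn(
            f"{n_excluded}/{replicates} replicates hit the event cap and were excluded",
            RuntimeWarning,
            stacklevel=2,
        )
    if used == 0:
        raise RuntimeError("all replicates hit the event cap")
    est = n_fixed / used
    return FixationEstimate(
        estimate=est,
        stderr=math.sqrt(max(est * (1.0 - est), 1.0 / used) / used) if used else float("nan"),
        n_fixed=n_fixed,
        n_lost=n_lost,
        n_extinct=n_extinct,
        n_excluded=n_excluded,
        replicates=replicates,
    )


def occupancy_histogram(
    ensemble: TrajectoryEnsemble | Trajectory,
    burn_in: float = 0.0,
    bins: int = 50,
) -> OccupancyHistogram:
    """Time-weighted histogram of p = N1/(N1+N2) from recorded trajectories.

    Each visited state is weighted by its holding time after ``burn_in``;
    realizations whose total population hits 0 inside the window contribute
    only their pre-extinction intervals (with a warning).  Requires
    trajectories recorded with ``record_every=1``.
    """
    records = ensemble.records if isinstance(ensemble, TrajectoryEnsemble) else [ensemble]
    edges = np.linspace(0.0, 1.0, bins + 1)
    weights = np.zeros(bins)
    total_time = 0.0
    for traj in records:
        if traj.times.size < 2:
            raise ValueError("trajectory has no recorded events (was record_every=1 used?)")
        if burn_in >= traj.final_time:
            raise ValueError("burn_in exceeds the trajectory length")
        t = traj.times
        tot = traj.counts.sum(axis=1)
        hold = np.diff(t)
        # clip intervals at the left to burn_in
        start = np.maximum(t[:-1], burn_in)
        hold = np.minimum(t[1:], traj.final_time) - start
        valid = (hold > 0) & (tot[:-1] > 0)
        if np.any((tot[:-1] == 0) & (hold > 0)):
            logger.warning("population hit 0 during the occupancy window; interval dropped")
        p = traj.counts[:-1, 0][valid] / tot[:-1][valid]
        idx = np.minimum((p * bins).astype(int), bins - 1)
        np.add.at(weights, idx, hold[valid])
        total_time += float(hold[valid].sum())
    if total_time <= 0:
        raise ValueError("no occupancy time after burn-in")
    return OccupancyHistogram(edges=edges, mass=weights / total_time, total_time=total_time)


def occupancy_ssa(
    model: ModelSpec,
    initial_counts,
    *,
    t_max: float,
    burn_in: float = 0.0,
    bins: int = 50,
    seed: int | None = None,
    replicates: int = 1,
) -> OccupancyHistogram:
    """Streaming occupancy histogram for long runs (no trajectory storage).

    Pools the time-weighted frequency occupancy of ``replicates`` independent
    realizations, each run to ``t_max`` with the first ``burn_in`` time units
    discarded.  Two-type models only.
    """
    if model.n_types != 2 or model.scalar_rates is None:
        raise ValueError("streaming occupancy is implemented for two-type built-in models")
    if burn_in >= t_max:
        raise ValueError("burn_in must be smaller than t_max")
    N0 = _validate_start(model, initial_counts)
    hist = np.zeros(bins)
    for ss in _child_seeds(seed, replicates):
        rng = np.random.default_rng(int(ss.generate_state(1)[0]))
        _run_two_type(
            model,
            int(N0[0]),
            int(N0[1]),
            t_max=t_max,
            until_absorption=False,
            event_cap=None,
            rng=rng,
            record_every=0,
            hist=hist,
            burn_in=burn_in,
        )
    total = float(hist.sum())
    if total <= 0:
        raise ValueError("no occupancy time accumulated")
    return OccupancyHistogram(
        edges=np.linspace(0.0, 1.0, bins + 1), mass=hist / total, total_time=total
    )
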