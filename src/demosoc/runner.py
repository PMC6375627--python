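"""Task execution: deterministic mapping (config, seed) -> artifact set.

Each run writes ``<out_prefix>.tsv`` (tab-separated table, '#'-prefixed
header lines carrying the config hash and library versions) and
``<out_prefix>.json`` (summary).  Outputs contain no timestamps, so the same
config and seed reproduce byte-identical files.  On a downstream numerical
error partial outputs are removed and the error propagates (nonzero exit in
the CLI).
"""

from __future__ import annotations

import json
import os
from typing import Any

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .config import RunConfig, config_hash, resolve_model
from .manifold import build_manifold
from .models import MODEL_FORMULAS
from .ssa import occupancy_ssa, simulate_ssa
from .sde import occupancy_frequency_sde, simulate_frequency_sde
from .stationary import favourability, stationary_density
from .experiments import mutation_sweep, optimal_social_action, reversal_scan

__all__ = ["run", "plan"]


def _versions() -> dict[str, str]:
    import scipy

    return {"demosoc": _pkg_version, "numpy": np.__version__, "scipy": scipy.__version__}


def _header_lines(config: RunConfig) -> str:
    meta = {"config_hash": config_hash(config), **_versions()}
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def _write_table(df: pd.DataFrame, path: str, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _write_summary(payload: dict, path: str, config: RunConfig) -> None:
    doc = {
        "config": config.model_dump(),
        "config_hash": config_hash(config),
        "versions": _versions(),
        "results": payload,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def plan(config: RunConfig) -> dict:
    """The resolved execution plan (what --dry-run prints)."""
    out: dict[str, Any] = {
        "task": config.task.name,
        "settings": config.task.settings,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "outputs": [f"{config.out_prefix}.tsv", f"{config.out_prefix}.json"],
    }
    if config.task.name != "list-models":
        model = resolve_model(config.model)
        out["model"] = {
            "family": model.name,
            "params": model.params,
            "omega": model.omega,
            "mu": model.mu,
            "epsilon": model.epsilon,
            "formula": model.formula,
        }
    return out


def run(config: RunConfig) -> dict:
    """Execute the configured task; returns the summary payload."""
    tsv = f"{config.out_prefix}.tsv"
    js = f"{config.out_prefix}.json"
    try:
        df, payload = _dispatch(config)
        _write_table(df, tsv, config)
        _write_summary(payload, js, config)
        return payload
    except Exception:
        for path in (tsv, js):
            if os.path.exists(path):
                os.remove(path)
        raise


def _dispatch(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    name = config.task.name
    s = dict(config.task.settings)
    seed = config.seed

    if name == "list-models":
        df = pd.DataFrame(
            [{"family": fam, "formula": desc} for fam, desc in MODEL_FORMULAS.items()]
        )
        return df, {"families": list(MODEL_FORMULAS)}

    if name == "optimal-nu":
        # nu is the optimization variable, so the model block need not carry it
        from .config import PRESETS

        block = config.model
        if block.preset is not None:
            base = PRESETS[block.preset]
            family = block.family or base["family"]
            params = dict(base["params"], **block.params)
        else:
            family, params = block.family, dict(block.params)
        params.pop("nu", None)
        res = optimal_social_action(family, params)
        _no_extra(s)
        df = pd.DataFrame(
            [
                {
                    "family": res.family,
                    "nu_star_closed": res.nu_star_closed,
                    "nu_star_numeric": res.nu_star_numeric,
                    "theta": res.theta,
                    "objective": res.objective,
                }
            ]
        )
        return df, {
            "nu_star_closed": res.nu_star_closed,
            "nu_star_numeric": res.nu_star_numeric,
            "theta": res.theta,
            "objective": res.objective,
            "boundary_optimum": res.boundary_optimum,
        }

    model = resolve_model(config.model)

    if name == "manifold":
        mf = build_manifold(model, num=int(s.pop("num", 401)))
        _no_extra(s)
        return mf.to_frame(), {"p_points": len(mf.p)}

    if name == "stationary":
        dist = stationary_density(model, grid_size=int(s.pop("grid_size", 2048)))
        _no_extra(s)
        payload: dict[str, Any] = {
            "integrable": dist.integrable,
            "boundary_exponents": list(dist.boundary_exponents),
        }
        if dist.integrable:
            rep = favourability(dist, model)
            payload["favourability"] = {
                "mass_above_half": rep.mass_above_half,
                "favoured": rep.favoured,
                "shape": rep.shape,
                "reversal": rep.reversal,
            }
            df = pd.DataFrame({"p": dist.p_grid, "density": dist.density})
        else:
            df = pd.DataFrame({"p": dist.p_grid, "log_unnormalized": dist.log_unnormalized})
        return df, payload

    if name == "simulate-ssa":
        counts = s.pop("initial_counts", None)
        if counts is None:
            p0 = float(s.pop("p0", 0.5))
            from .manifold import quasi_equilibrium_density

            n0 = quasi_equilibrium_density(model, p0)
            total = int(round(model.omega * n0))
            n1 = int(round(p0 * total))
            counts = [n1, total - n1]
        traj = simulate_ssa(
            model,
            counts,
            t_max=s.pop("t_max", None),
            until_absorption=bool(s.pop("until_absorption", False)),
            event_cap=s.pop("event_cap", None),
            seed=seed,
            record_every=int(s.pop("record_every", 1)),
        )
        _no_extra(s)
        df = pd.DataFrame(
            {"time": traj.times, **{f"N{i+1}": traj.counts[:, i] for i in range(model.n_types)}}
        )
        return df, {
            "stop_reason": traj.stop_reason,
            "n_events": traj.n_events,
            "final_time": traj.final_time,
            "final_counts": traj.final_counts.tolist(),
            "seed": seed,
        }

    if name == "simulate-sde":
        p0 = float(s.pop("p0", 0.5))
        t_max = float(s.pop("t_max"))
        bins = int(s.pop("bins", 50))
        replicates = int(s.pop("replicates", 1))
        dt = s.pop("dt", None)
        burn_in = float(s.pop("burn_in", 0.0))
        path = simulate_frequency_sde(
            model, p0, t_max=t_max, dt=dt, seed=seed, replicates=replicates
        )
        hist = occupancy_frequency_sde(
            model,
            p0,
            t_max=t_max,
            burn_in=burn_in,
            bins=bins,
            dt=dt,
            seed=seed,
            replicates=replicates,
        )
        _no_extra(s)
        df = pd.DataFrame({"bin_center": hist.centers, "occupancy": hist.mass})
        return df, {
            "dt": path.dt,
            "boundary_hits": path.boundary_hits,
            "final_mean_p": float(np.mean(path.final)),
            "seed": seed,
        }

    if name == "scan-reversal":
        omegas = [float(v) for v in s.pop("omega_values")]
        epsilons = [float(v) for v in s.pop("epsilon_values")]
        df = reversal_scan(model, omegas, epsilons, grid_size=int(s.pop("grid_size", 2048)))
        _no_extra(s)
        return df, {
            "n_cells": len(df),
            "n_reversals": int(df["reversal"].sum()),
        }

    if name == "sweep-mu":
        mus = [float(v) for v in s.pop("mu_values")]
        df = mutation_sweep(model, mus, grid_size=int(s.pop("grid_size", 2048)))
        _no_extra(s)
        return df, {"shapes": df["shape"].tolist()}

    if name == "compare":
        # SSA occupancy against the analytic stationary density
        t_max = float(s.pop("t_max"))
        burn_in = float(s.pop("burn_in", 0.0))
        bins = int(s.pop("bins", 25))
        replicates = int(s.pop("replicates", 1))
        p0 = float(s.pop("p0", 0.5))
        _no_extra(s)
        from .manifold import quasi_equilibrium_density

        n0 = quasi_equilibrium_density(model, p0)
        total = int(round(model.omega * n0))
        n1 = int(round(p0 * total))
        hist = occupancy_ssa(
            model,
            [n1, total - n1],
            t_max=t_max,
            burn_in=burn_in,
            bins=bins,
            seed=seed,
            replicates=replicates,
        )
        dist = stationary_density(model)
        analytic = _bin_masses(dist, hist.edges)
        tv = 0.5 * float(np.abs(hist.mass - analytic).sum())
        df = pd.DataFrame(
            {"bin_center": hist.centers, "empirical": hist.mass, "analytic": analytic}
        )
        return df, {"total_variation": tv, "simulated_time": hist.total_time, "seed": seed}

    raise ValueError(f"unknown task {name!r}")


def _bin_masses(dist, edges: np.ndarray) -> np.ndarray:
    """Analytic stationary mass per histogram bin (trapezoid on a fine grid)."""
    masses = np.empty(len(edges) - 1)
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        lo_c = max(float(lo), float(dist.p_grid[0]))
        hi_c = min(float(hi), float(dist.p_grid[-1]))
        q = np.linspace(lo_c, hi_c, 200)
        masses[i] = np.trapezoid(dist.pdf(q), q)
    return masses / masses.sum()


def _no_extra(settings: dict) -> None:
    if settings:
        raise ValueError(f"unknown task settings: {sorted(settings)}")
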