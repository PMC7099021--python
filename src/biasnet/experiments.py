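"""Seeded ensemble drivers and figure-level reproductions.

Each driver builds networks and signals from a :class:`ModelConfig`, runs the
deterministic engine, and returns tidy pandas tables together with a metadata
dict (config, per-repetition seeds, convention flags) sufficient to reproduce
every number bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import meanfield
from .config import ModelConfig
from .dynamics import SteadyState, run_deterministic
from .netgen import Network, make_model_network


@dataclass
class GroupSummary:
    """Mix/orientation summary of a node group.

    ``z_group`` is the polarization: the fraction of the group holding the
    minority orientation (0 at consensus, 0.5 maximal).
    """

    x_group: float
    y_group: float
    z_group: float
    y_biased_frac: float = float("nan")


@dataclass
class PhaseDiagramResult:
    """Grid of mean steady-state unbiased mixes over (Ŷ_B(0), q)."""

    table: pd.DataFrame
    boundaries: pd.DataFrame
    meta: dict = field(default_factory=dict)


def polarization(orientations) -> float:
    """Minority-orientation fraction min(y_C, 1 - y_C) of a group."""
    y = np.asarray(orientations)
    if y.size == 0:
        raise ValueError("polarization of an empty group is undefined")
    frac_pos = float(np.mean(y > 0))
    return min(frac_pos, 1.0 - frac_pos)


def group_summary(steady_state: SteadyState, nodes) -> GroupSummary:
    nodes = sorted(nodes)
    if not nodes:
        raise ValueError("empty group")
    y = steady_state.y_star[nodes]
    frac_pos = float(np.mean(y > 0))
    return GroupSummary(
        x_group=float(np.mean(steady_state.x_star[nodes])),
        y_group=frac_pos,
        z_group=min(frac_pos, 1.0 - frac_pos),
        y_biased_frac=steady_state.y_biased_frac,
    )


def realized_accuracy(steady_state: SteadyState, network: Network) -> float:
    """Fraction of unbiased agents whose final orientation matches X = +1."""
    unbiased = sorted(network.unbiased)
    if not unbiased:
        raise ValueError("accuracy undefined: network has no unbiased agents")
    return float(np.mean(steady_state.y_star[unbiased] > 0))


def _spawn_seeds(seed: int, count: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(count) % 2**31]


def run_once(config: ModelConfig, *, force_y_biased_init: float | None = None,
             **run_kwargs):
    """Build a network from the config and run the deterministic engine."""
    net, signals = make_model_network(config, force_y_biased_init=force_y_biased_init)
    state = run_deterministic(
        net, config.q, signals, tol=config.tol, max_iter=config.max_iter, **run_kwargs
    )
    return net, signals, state


def sweep_phase_diagram(
    config: ModelConfig,
    y_grid,
    q_grid,
    reps: int = 10,
    seed: int = 0,
    consensus_eps: float = 0.05,
) -> PhaseDiagramResult:
    """Phase diagram over (Ŷ_B(0), q): mean final unbiased mix per cell.

    For each cell, ``reps`` networks are generated with the biased agents'
    initial signals forced to the nearest achievable positive fraction
    round(Ŷ·|B|)/|B| (unbiased agents draw from p). A repetition counts as
    consensus when every agent ends on the same orientation. Cells carry the
    analytic cascade classification for comparison.
    """
    y_grid = [float(y) for y in y_grid]
    q_grid = [float(q) for q in q_grid]
    rows = []
    seeds = _spawn_seeds(seed, len(y_grid) * len(q_grid) * reps)
    it = iter(seeds)
    for q in q_grid:
        cfg_q = config.replace(q=q)
        for y0 in y_grid:
            finals, consensus = [], 0
            for _ in range(reps):
                cfg = cfg_q.replace(seed=next(it))
                net, _, state = run_once(cfg, force_y_biased_init=y0)
                unbiased = sorted(net.unbiased)
                x_u = float(np.mean(state.x_star[unbiased])) if unbiased else float(
                    np.mean(state.x_star)
                )
                finals.append(x_u)
                if polarization(state.y_star) == 0.0:
                    consensus += 1
            mean_x = float(np.mean(finals))
            rows.append(
                {
                    "y_biased_init": y0,
                    "q": q,
                    "mean_x_u": mean_x,
                    "reps": reps,
                    "consensus_fraction": consensus / reps,
                    "predicted_x_u": meanfield.predict_unbiased_mix(y0, q),
                    "observed_class": _classify(mean_x, consensus_eps),
                    "predicted_class": _classify(
                        meanfield.predict_unbiased_mix(y0, q), consensus_eps
                    ),
                }
            )
    boundaries = pd.DataFrame(
        {
            "q": q_grid,
            "lower": [meanfield.cascade_boundaries(q)[0] for q in q_grid],
            "upper": [meanfield.cascade_boundaries(q)[1] for q in q_grid],
        }
    )
    meta = {"config": config.to_dict(), "seed": seed, "reps": reps,
            "consensus_eps": consensus_eps}
    return PhaseDiagramResult(table=pd.DataFrame(rows), boundaries=boundaries, meta=meta)


def _classify(x: float, eps: float) -> str:
    if x >= 1.0 - eps:
        return "consensus-1"
    if x <= eps:
        return "consensus-0"
    return "mixed"


def ensemble_run(
    config: ModelConfig,
    reps: int = 10,
    seed: int = 0,
    force_y_biased_init: float | None = None,
) -> dict:
    """Distribution of individual unbiased steady-state mixes over an ensemble.

    Pools the unbiased agents' x_i* across ``reps`` runs and compares their
    empirical variance with the analytic individual-mix variance evaluated at
    each run's realized mean (the bias–connectivity trade-off formula).
    """
    seeds = _spawn_seeds(seed, reps)
    samples, per_run = [], []
    for s in seeds:
        cfg = config.replace(seed=s)
        net, _, state = run_once(cfg, force_y_biased_init=force_y_biased_init)
        unbiased = sorted(net.unbiased)
        xs = state.x_star[unbiased]
        samples.append(xs)
        mean = float(np.mean(xs))
        per_run.append(
            {
                "seed": s,
                "mean_x_u": mean,
                "var_x_u": float(np.var(xs)),
                "predicted_var": meanfield.individual_mix_variance(
                    mean, config.f, config.q, config.k
                ),
                "y_biased_frac": state.y_biased_frac,
                "t_star": state.t_star,
                "converged": state.converged,
            }
        )
    pooled = np.concatenate(samples)
    table = pd.DataFrame(per_run)
    return {
        "samples": pooled,
        "per_run": table,
        "mean": float(np.mean(pooled)),
        "variance": float(np.var(pooled)),
        "meta": {"config": config.to_dict(), "seed": seed, "seeds": seeds},
    }


def accuracy_experiment(
    config: ModelConfig,
    f_grid=None,
    k_grid=None,
    p_grid=None,
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated vs analytic accuracy along a parameter sweep.

    Exactly one of ``f_grid``, ``k_grid``, ``p_grid`` must be given. Each grid
    point runs ``reps`` seeded simulations and reports the mean realized
    accuracy with its standard error next to the analytic expectation
    (closed form at f = 0; quadrature otherwise, requiring q > 1/2).
    """
    grids = [g is not None for g in (f_grid, k_grid, p_grid)]
    if sum(grids) != 1:
        raise ValueError("give exactly one of f_grid, k_grid, p_grid")
    if f_grid is not None:
        axis, values = "f", list(f_grid)
    elif k_grid is not None:
        axis, values = "k", list(k_grid)
    else:
        axis, values = "p", list(p_grid)
    rows = []
    seeds = _spawn_seeds(seed, len(values) * reps)
    it = iter(seeds)
    for v in values:
        cfg_v = config.replace(**{axis: v})
        accs = []
        for _ in range(reps):
            cfg = cfg_v.replace(seed=next(it))
            net, _, state = run_once(cfg)
            accs.append(realized_accuracy(state, net))
        if cfg_v.f == 0.0:
            analytic = meanfield.accuracy_unbiased(cfg_v.n, cfg_v.p)
        elif cfg_v.q > 0.5:
            analytic = meanfield.expected_accuracy(
                cfg_v.n, cfg_v.p, cfg_v.f, cfg_v.q, cfg_v.k
            )
        else:
            analytic = float("nan")
        rows.append(
            {
                axis: v,
                "simulated_accuracy": float(np.mean(accs)),
                "stderr": float(np.std(accs, ddof=1) / np.sqrt(len(accs)))
                if len(accs) > 1
                else 0.0,
                "analytic_accuracy": analytic,
                "reps": reps,
            }
        )
    return pd.DataFrame(rows)
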