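"""Signal-exchange dynamics: stochastic engine and deterministic ghost-node model.

Agents accumulate ±1 signals. Agent i's *signal mix* is

    x_i(t) = N_i^+(t) / (N_i^+(t) + N_i^-(t)),

and its *orientation* y_i(t) is the sign of x_i(t) - 1/2 (the Bayes-naive
best guess of the ground truth). At each step all agents synchronously share
their full signal sets with their neighbours. Unbiased agents accept incoming
signals as-is; a biased agent rejects each incongruent incoming signal
(s = -y_i) with probability q and stores a congruent one instead.

The deterministic counterpart augments the network with two *ghost* nodes
whose mixes are pinned at 1 and 0. Each biased agent re-routes weight kq/(k+1)
of its update to the ghost matching its current orientation, giving the
row-stochastic (n+2)x(n+2) update x̂(t) = Â(t) x̂(t-1). Whenever a biased
agent's mix crosses 1/2 its ghost link swaps sides, so Â is piecewise
constant in time; t* is the last step at which any such swap happens.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .netgen import Network

logger = logging.getLogger(__name__)

#: largest exact total signal count before the stochastic engine switches to
#: its Gaussian (fraction-tracking) approximation
EXACT_COUNT_LIMIT = 2**40


@dataclass
class AgentState:
    """Signal counts and derived quantities for one agent."""

    n_pos: int
    n_neg: int
    y: int
    is_biased: bool = False

    @property
    def x(self) -> float:
        return signal_mix(self.n_pos, self.n_neg)


@dataclass
class SteadyState:
    """Result of a dynamics run.

    ``t_star`` is the last step index at which any biased agent switched
    orientation (0 if none ever did). ``y_biased_frac`` is Ŷ_B*, the final
    fraction of positively oriented biased agents (NaN when f = 0).
    """

    x_star: np.ndarray
    y_star: np.ndarray
    t_star: int
    y_biased_frac: float
    converged: bool
    iterations: int
    trajectory: list | None = None
    x_history: list | None = None
    meta: dict = field(default_factory=dict)


def signal_mix(n_pos, n_neg) -> float:
    """Fraction of positive signals, N+/(N+ + N-). Errors if both are zero."""
    if n_pos < 0 or n_neg < 0:
        raise ValueError("signal counts must be non-negative")
    total = n_pos + n_neg
    if total == 0:
        raise ValueError("signal mix undefined: agent holds no signals")
    x = n_pos / total
    if n_pos == n_neg:
        warnings.warn("degenerate signal mix x = 1/2 (tied counts)", stacklevel=2)
    return x


def orientation(x: float, previous: int = 1) -> int:
    """Orientation sign(x - 1/2); exact ties keep the previous orientation.

    The model is normally run on configurations that rule out x = 1/2; a tie
    indicates a degenerate configuration and is logged.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"signal mix must lie in [0, 1], got {x}")
    if x > 0.5:
        return 1
    if x < 0.5:
        return -1
    warnings.warn(
        "signal mix exactly 1/2: retaining previous orientation", stacklevel=2
    )
    return int(previous)


def _orientations_from_mixes(x: np.ndarray, previous: np.ndarray) -> np.ndarray:
    y = np.where(x > 0.5, 1, np.where(x < 0.5, -1, 0)).astype(np.int8)
    ties = y == 0
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} agents at the degenerate mix x = 1/2; "
            "retaining previous orientations",
            stacklevel=2,
        )
        y[ties] = previous[ties]
    return y


def build_update_matrix(network: Network, q: float, orientations: np.ndarray) -> np.ndarray:
    """Explicit (n+2)x(n+2) row-stochastic ghost-node update matrix Â.

    Row i of an unbiased agent places weight 1/(k_i+1) on itself and each
    neighbour. A biased agent down-weights neighbours to (1-q)/(k_i+1) and
    places k_i q/(k_i+1) on the ghost matching its orientation (index n for
    the positive ghost, n+1 for the negative one). Ghost rows are identity
    rows, pinning the ghost mixes at 1 and 0.
    """
    n = network.n
    deg = network.degree
    biased = network.biased_mask()
    A = np.zeros((n + 2, n + 2))
    w_self = 1.0 / (deg + 1.0)
    adj = network.adjacency().toarray().astype(float)
    # neighbour weights: 1/(k_i+1), reduced by (1-q) on biased rows
    nb_scale = np.where(biased, (1.0 - q), 1.0) * w_self
    A[:n, :n] = adj * nb_scale[:, None]
    A[np.arange(n), np.arange(n)] = w_self
    ghost_w = deg * q * w_self
    pos_rows = biased & (np.asarray(orientations) > 0)
    neg_rows = biased & (np.asarray(orientations) < 0)
    A[np.where(pos_rows)[0], n] = ghost_w[pos_rows]
    A[np.where(neg_rows)[0], n + 1] = ghost_w[neg_rows]
    A[n, n] = 1.0
    A[n + 1, n + 1] = 1.0
    return A


def step_deterministic(x_vec: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """One synchronous update x̂(t) = Â x̂(t-1) of the augmented mix vector."""
    x_vec = np.asarray(x_vec, dtype=float)
    if x_vec.shape[0] != matrix.shape[0]:
        raise ValueError("augmented vector and matrix sizes differ")
    return matrix @ x_vec


def run_deterministic(
    network: Network,
    q: float,
    initial_signals: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    record_trajectory: bool = False,
    record_agent_mixes: bool = False,
) -> SteadyState:
    """Iterate the ghost-node DeGroot dynamics to a steady state.

    Initial mixes are x_i(0) = 1 for s_i = +1 and 0 for s_i = -1; initial
    orientations equal the initial signals. After every step all orientations
    are recomputed; a biased orientation flip swaps that agent's ghost link.
    Convergence requires a max-norm step change below ``tol`` together with
    zero orientation flips in the final step. Non-convergence within
    ``max_iter`` is flagged, not raised.

    The update is evaluated in vectorised sparse form; it is mathematically
    identical to multiplying by :func:`build_update_matrix`.
    """
    n = network.n
    signals = np.asarray(initial_signals)
    if signals.shape[0] != n:
        raise ValueError("one initial signal per agent required")
    deg = network.degree.astype(float)
    biased = network.biased_mask()
    biased_idx = np.where(biased)[0]
    adj = network.adjacency().astype(float)

    x = (signals > 0).astype(float)
    y = np.where(signals > 0, 1, -1).astype(np.int8)

    inv_kp1 = 1.0 / (deg + 1.0)
    nb_scale = np.where(biased, 1.0 - q, 1.0) * inv_kp1
    ghost_amp = deg * q * inv_kp1  # weight on the orientation-aligned ghost

    t_star = 0
    converged = False
    iterations = 0
    traj = [] if record_trajectory else None
    if record_trajectory:
        traj.append(_group_summary(0, x, y, biased))
    x_history = [x.copy()] if record_agent_mixes else None

    for t in range(1, max_iter + 1):
        ghost_target = np.where(biased, (y > 0).astype(float), 0.0)
        x_new = inv_kp1 * x + nb_scale * (adj @ x) + ghost_amp * ghost_target
        y_new = _orientations_from_mixes(x_new, y)
        flips = (y_new != y) & biased
        if flips.any():
            t_star = t
        step_change = float(np.max(np.abs(x_new - x)))
        x, y = x_new, y_new
        iterations = t
        if record_trajectory:
            traj.append(_group_summary(t, x, y, biased))
        if record_agent_mixes:
            x_history.append(x.copy())
        if step_change < tol and not flips.any():
            converged = True
            break

    y_biased_frac = float(np.mean(y[biased_idx] > 0)) if biased_idx.size else float("nan")
    return SteadyState(
        x_star=x,
        y_star=y,
        t_star=t_star,
        y_biased_frac=y_biased_frac,
        converged=converged,
        iterations=iterations,
        trajectory=traj,
        x_history=x_history,
        meta={"engine": "deterministic", "q": q, "tol": tol, "max_iter": max_iter},
    )


def _group_summary(t: int, x: np.ndarray, y: np.ndarray, biased: np.ndarray) -> dict:
    unbiased = ~biased
    pos_b = biased & (y > 0)
    neg_b = biased & (y < 0)

    def _mean(mask, arr):
        return float(np.mean(arr[mask])) if mask.any() else float("nan")

    y_b = _mean(biased, (y > 0).astype(float))
    y_u = _mean(unbiased, (y > 0).astype(float))
    return {
        "t": t,
        "x_U": _mean(unbiased, x),
        "x_Bpos": _mean(pos_b, x),
        "x_Bneg": _mean(neg_b, x),
        "Y_B": y_b,
        "z_U": min(y_u, 1.0 - y_u) if unbiased.any() else float("nan"),
    }


def run_stochastic(
    network: Network,
    q: float,
    initial_signals: np.ndarray,
    seed: int,
    t_max: int = 50,
    record_trajectory: bool = False,
    record_agent_mixes: bool = False,
) -> SteadyState:
    """Exact stochastic signal-exchange dynamics.

    Signal counts are integers; each step every agent receives the full
    current count set of every neighbour. A biased agent with orientation y
    flips Binomial(M, q) of the M incongruent incoming signals to congruent
    ones before storing them; its own stored signals are never re-distorted.
    On a k-regular graph every agent's total count after t steps is exactly
    (k+1)^t.

    Counts are tracked exactly while the largest total is below
    ``EXACT_COUNT_LIMIT`` (2^40); beyond that the engine switches to tracking
    real-valued counts with Gaussian-approximated binomial distortion noise
    (logged). The run stops at ``t_max`` (flagged as non-converged if the
    final step still changed any orientation).
    """
    n = network.n
    signals = np.asarray(initial_signals)
    rng = np.random.default_rng(seed)
    adj = network.adjacency()  # int64 csr
    biased = network.biased_mask()
    biased_idx = np.where(biased)[0]

    n_pos = (signals > 0).astype(np.int64)
    n_neg = (signals < 0).astype(np.int64)
    y = np.where(signals > 0, 1, -1).astype(np.int8)
    exact = True
    t_star = 0
    last_flip_free = False
    traj = [] if record_trajectory else None
    if record_trajectory:
        traj.append(_group_summary(0, n_pos / (n_pos + n_neg), y, biased))
    x_history = [n_pos / (n_pos + n_neg)] if record_agent_mixes else None

    for t in range(1, t_max + 1):
        if exact and (n_pos + n_neg).max() * (network.degree.max() + 1) > EXACT_COUNT_LIMIT:
            exact = False
            logger.info(
                "step %d: totals exceed 2^40, switching to Gaussian-approximated "
                "fraction tracking",
                t,
            )
            n_pos = n_pos.astype(float)
            n_neg = n_neg.astype(float)
        inc_pos = adj @ n_pos
        inc_neg = adj @ n_neg
        # distortion of incoming incongruent signals by biased agents
        pos_b = biased_idx[y[biased_idx] > 0]
        neg_b = biased_idx[y[biased_idx] < 0]
        if exact:
            flip_pos = rng.binomial(inc_neg[pos_b], q)  # -1 -> +1
            flip_neg = rng.binomial(inc_pos[neg_b], q)  # +1 -> -1
        else:
            flip_pos = q * inc_neg[pos_b] + rng.normal(
                0.0, np.sqrt(np.maximum(q * (1 - q) * inc_neg[pos_b], 0.0))
            )
            flip_pos = np.clip(flip_pos, 0.0, inc_neg[pos_b])
            flip_neg = q * inc_pos[neg_b] + rng.normal(
                0.0, np.sqrt(np.maximum(q * (1 - q) * inc_pos[neg_b], 0.0))
            )
            flip_neg = np.clip(flip_neg, 0.0, inc_pos[neg_b])
        inc_pos = inc_pos.astype(n_pos.dtype)
        inc_neg = inc_neg.astype(n_pos.dtype)
        inc_pos[pos_b] += flip_pos.astype(n_pos.dtype)
        inc_neg[pos_b] -= flip_pos.astype(n_pos.dtype)
        inc_neg[neg_b] += flip_neg.astype(n_pos.dtype)
        inc_pos[neg_b] -= flip_neg.astype(n_pos.dtype)
        n_pos = n_pos + inc_pos
        n_neg = n_neg + inc_neg
        x = n_pos / (n_pos + n_neg)
        y_new = _orientations_from_mixes(x, y)
        flips = (y_new != y) & biased
        if flips.any():
            t_star = t
        last_flip_free = not flips.any()
        y = y_new
        if record_trajectory:
            traj.append(_group_summary(t, x, y, biased))
        if record_agent_mixes:
            x_history.append(np.asarray(x, dtype=float))

    x = n_pos / (n_pos + n_neg) if t_max > 0 else (signals > 0).astype(float)
    y_biased_frac = float(np.mean(y[biased_idx] > 0)) if biased_idx.size else float("nan")
    return SteadyState(
        x_star=np.asarray(x, dtype=float),
        y_star=y,
        t_star=t_star,
        y_biased_frac=y_biased_frac,
        converged=bool(last_flip_free),
        iterations=t_max,
        trajectory=traj,
        x_history=x_history,
        meta={"engine": "stochastic", "q": q, "seed": seed, "t_max": t_max,
              "exact_counts": exact},
    )


def influence_matrix_limit(matrix: np.ndarray, tol: float = 1e-12, max_squarings: int = 80) -> np.ndarray:
    """Limiting influence matrix Â* = lim_t Â^t by repeated squaring.

    For the model's matrices the limit always exists: unbiased connected
    k-regular networks converge to a*_ij = 1/n; biased networks (q > 0)
    converge to a matrix whose agent-to-agent block vanishes, with each
    agent's influence weight split between the two ghost nodes.
    """
    M = np.asarray(matrix, dtype=float)
    for _ in range(max_squarings):
        M2 = M @ M
        if np.max(np.abs(M2 - M)) < tol:
            return M2
        M = M2
    raise RuntimeError(
        f"influence matrix did not converge within {max_squarings} squarings"
    )
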