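"""Network construction, biased-agent assignment and initial signals.

Networks are undirected, simple and connected. Four generators are supported,
all parameterised so that ``k`` is the (mean) degree:

- ``k-regular``: uniform-ish random k-regular graph (pairing model).
- ``erdos-renyi``: G(n, p_edge) with p_edge = k/(n-1).
- ``barabasi-albert``: preferential attachment with m = k/2 edges per node.
- ``small-world``: Watts–Strogatz ring with base degree k, rewiring 0.1.

A fraction ``f`` of agents is designated *biased* (the set B); the biased set
has exactly ``round(f*n)`` members, drawn uniformly at random. Initial signals
are i.i.d. ±1 with ``Prob(+1) = p`` (ground truth fixed to X = +1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .config import TOPOLOGIES, validate_p

logger = logging.getLogger(__name__)

#: rewiring probability of the small-world (Watts–Strogatz) generator
SMALL_WORLD_REWIRING = 0.1

#: attempts at drawing a connected graph before giving up
MAX_CONNECT_RETRIES = 100


@dataclass
class Network:
    """An agent graph plus its biased subset.

    Attributes
    ----------
    graph : networkx.Graph
        Undirected simple connected graph on nodes ``0..n-1``.
    biased : frozenset[int]
        The biased agents B; the complement is the unbiased set U.
    meta : dict
        Generation metadata (topology, seed actually used, generator
        defaults) echoed into result files.
    """

    graph: nx.Graph
    biased: frozenset = frozenset()
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edges(self) -> set:
        return {(min(u, v), max(u, v)) for u, v in self.graph.edges()}

    @property
    def degree(self) -> np.ndarray:
        return np.asarray([self.graph.degree(i) for i in range(self.n)], dtype=np.int64)

    @property
    def unbiased(self) -> frozenset:
        return frozenset(range(self.n)) - self.biased

    def biased_mask(self) -> np.ndarray:
        mask = np.zeros(self.n, dtype=bool)
        mask[list(self.biased)] = True
        return mask

    def adjacency(self) -> sp.csr_matrix:
        """Sparse adjacency matrix in CSR form (0/1 entries, int64)."""
        return nx.to_scipy_sparse_array(
            self.graph, nodelist=range(self.n), dtype=np.int64, format="csr"
        )


def _generate_once(topology: str, n: int, k: int, seed: int) -> nx.Graph:
    if topology == "k-regular":
        return nx.random_regular_graph(k, n, seed=seed)
    if topology == "erdos-renyi":
        return nx.gnp_random_graph(n, k / (n - 1), seed=seed)
    if topology == "barabasi-albert":
        m = max(1, k // 2)
        return nx.barabasi_albert_graph(n, m, seed=seed)
    if topology == "small-world":
        return nx.watts_strogatz_graph(n, k, SMALL_WORLD_REWIRING, seed=seed)
    raise ValueError(f"unknown topology {topology!r}; expected one of {TOPOLOGIES}")


def make_network(topology: str, n: int, k: int, seed: int) -> Network:
    """Construct a connected simple graph with n nodes and (mean) degree k.

    ``k`` is the exact degree for ``k-regular`` and the target mean degree for
    the other topologies. Disconnected draws are retried with derived seeds
    (up to ``MAX_CONNECT_RETRIES``); an error is raised if no connected graph
    is found.
    """
    if n <= 0 or k <= 0 or k >= n:
        raise ValueError(f"need 0 < k < n, got n={n}, k={k}")
    if topology == "k-regular" and (n * k) % 2 != 0:
        raise ValueError(f"a k-regular graph needs n*k even (n={n}, k={k})")
    # deterministic retry ladder derived from the user seed
    child_seeds = np.random.SeedSequence(seed).generate_state(MAX_CONNECT_RETRIES)
    for attempt, s in enumerate(child_seeds):
        g = _generate_once(topology, n, k, int(s % 2**31))
        if nx.is_connected(g):
            meta = {
                "topology": topology,
                "n": n,
                "k": k,
                "seed": seed,
                "attempts": attempt + 1,
            }
            if topology == "barabasi-albert":
                meta["ba_m"] = max(1, k // 2)
            if topology == "small-world":
                meta["rewiring"] = SMALL_WORLD_REWIRING
            if attempt:
                logger.info("regenerated %d times to obtain a connected graph", attempt)
            return Network(graph=g, meta=meta)
    raise RuntimeError(
        f"could not generate a connected {topology} graph with n={n}, k={k} "
        f"after {MAX_CONNECT_RETRIES} attempts (seed={seed})"
    )


def assign_bias(network: Network, f: float, seed: int) -> frozenset:
    """Draw the biased set B: a uniform subset of exactly round(f*n) nodes.

    The count is exact (not Bernoulli per node). Returns the set and stores it
    on ``network.biased``.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"f must lie in [0, 1], got {f}")
    n = network.n
    n_biased = int(round(f * n))
    rng = np.random.default_rng(seed)
    chosen = frozenset(int(i) for i in rng.choice(n, size=n_biased, replace=False))
    network.biased = chosen
    network.meta.update({"f": f, "bias_seed": seed, "n_biased": n_biased})
    return chosen


def draw_initial_signals(n: int, p: float, seed: int) -> np.ndarray:
    """i.i.d. initial signals s_i = ±1 with Prob(+1) = p (X = +1 fixed)."""
    validate_p(p)
    rng = np.random.default_rng(seed)
    return np.where(rng.random(n) < p, 1, -1).astype(np.int8)


def make_model_network(config, *, force_y_biased_init: float | None = None):
    """Convenience: build (network, signals) from a :class:`ModelConfig`.

    Derives independent child seeds for graph generation, bias assignment and
    signal drawing from ``config.seed``. When ``force_y_biased_init`` is
    given, the initial signals of biased agents are overridden so that exactly
    ``round(y * |B|)`` of them are +1 (unbiased agents still draw from p);
    the realised fraction is recorded in ``network.meta``.
    """
    ss = np.random.SeedSequence(config.seed).generate_state(4) % 2**31
    net = make_network(config.topology, config.n, config.k, int(ss[0]))
    assign_bias(net, config.f, int(ss[1]))
    signals = draw_initial_signals(config.n, config.p, int(ss[2]))
    if force_y_biased_init is not None:
        biased = sorted(net.biased)
        n_b = len(biased)
        n_pos = int(round(force_y_biased_init * n_b))
        rng = np.random.default_rng(int(ss[3]))
        order = rng.permutation(n_b)
        signals[np.asarray(biased)[order[:n_pos]]] = 1
        signals[np.asarray(biased)[order[n_pos:]]] = -1
        net.meta["y_biased_init_target"] = force_y_biased_init
        net.meta["y_biased_init_realized"] = n_pos / n_b if n_b else float("nan")
    return net, signals
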