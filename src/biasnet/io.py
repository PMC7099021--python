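"""Reading and writing networks, signals and results.

Graphs travel as whitespace-delimited edge lists (0-based node ids, one edge
per line) or GraphML; the biased set as one node id per line; signals as a
two-column CSV (node_id, signal). Steady states are written as a CSV of
per-agent rows plus a JSON metadata sidecar carrying the configuration, the
seeds used, and convention flags.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .dynamics import SteadyState
from .netgen import Network


def write_edge_list(network: Network, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(network.edges):
            fh.write(f"{u} {v}\n")


def read_edge_list(path) -> Network:
    g = nx.read_edgelist(path, nodetype=int)
    g.add_nodes_from(range(max(g.nodes) + 1))
    return Network(graph=nx.Graph(g), meta={"source": str(path)})


def write_graphml(network: Network, path) -> None:
    g = network.graph.copy()
    for node in g.nodes:
        g.nodes[node]["biased"] = node in network.biased
    nx.write_graphml(g, path)


def read_graphml(path) -> Network:
    g = nx.read_graphml(path, node_type=int)
    biased = frozenset(n for n, d in g.nodes(data=True) if d.get("biased"))
    return Network(graph=nx.Graph(g), biased=biased, meta={"source": str(path)})


def write_biased_set(network: Network, path) -> None:
    with open(path, "w") as fh:
        for node in sorted(network.biased):
            fh.write(f"{node}\n")


def read_biased_set(path) -> frozenset:
    text = Path(path).read_text().split()
    return frozenset(int(tok) for tok in text)


def write_signals(signals, path) -> None:
    pd.DataFrame(
        {"node_id": np.arange(len(signals)), "signal": np.asarray(signals)}
    ).to_csv(path, index=False)


def read_signals(path) -> np.ndarray:
    df = pd.read_csv(path).sort_values("node_id")
    return df["signal"].to_numpy(dtype=np.int8)


def write_steady_state(state: SteadyState, network: Network, path_csv,
                       path_json=None) -> None:
    biased = network.biased_mask()
    pd.DataFrame(
        {
            "agent_id": np.arange(network.n),
            "is_biased": biased,
            "x_star": state.x_star,
            "y_star": state.y_star,
        }
    ).to_csv(path_csv, index=False)
    sidecar = {
        "t_star": state.t_star,
        "y_biased_frac": state.y_biased_frac,
        "converged": state.converged,
        "iterations": state.iterations,
        "network_meta": _jsonable(network.meta),
        "run_meta": _jsonable(state.meta),
    }
    if path_json is None:
        path_json = str(path_csv) + ".json"
    with open(path_json, "w") as fh:
        json.dump(sidecar, fh, indent=2)


def write_trajectory(state: SteadyState, path) -> None:
    if state.trajectory is None:
        raise ValueError("run was executed without record_trajectory=True")
    pd.DataFrame(state.trajectory).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
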