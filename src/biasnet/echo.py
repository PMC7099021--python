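"""Echo-chamber detection and the permeability relation.

An echo chamber C is a connected set of unbiased agents enclosed by biased
agents: every member's neighbourhood lies inside C or in the biased set B,
every member has at least one neighbour inside C, and every member is in
direct contact with the biased boundary ∂_C (the biased agents adjacent to
C). Biased boundary agents gatekeep the information flowing into the
chamber; the confirmation-bias parameter q sets the chamber's permeability,

    x_C* ≈ q x_∂C* + (1-q) x_U*,

a weighted average of the boundary's own mix and the global unbiased mix.

Conventions (recorded in report metadata): chambers have at least two
members; an unbiased node whose neighbours are all biased is counted
separately as an *isolated* node; a connected set with no biased boundary
(e.g. the whole network at f = 0) is not a chamber; and a chamber is a
*minority* pocket, comprising at most half of the unbiased population. The
minority condition is what ties chambers to percolation: an echo chamber is
a group whose information set can be unrepresentative of the broader
network, so the bulk of unbiased society — the giant component of the
unbiased subgraph, which is infinite in the percolation limit — is never a
chamber. With it, the chamber fraction η_C grows with the biased fraction f
and shrinks with connectivity k, as the fraction of unbiased agents in
finite clusters does when bias fragments the unbiased subgraph and extra
connectivity re-knits it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .dynamics import SteadyState
from .netgen import Network

CONVENTIONS = {
    "min_size": 2,
    "boundary_nonempty": True,
    "max_fraction_of_unbiased": 0.5,
}


@dataclass
class EchoChamber:
    """A detected chamber: members C, biased boundary ∂_C, and mix summaries."""

    members: frozenset
    boundary: frozenset
    x_members: float = float("nan")
    x_boundary: float = float("nan")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class EchoReport:
    """All chambers of a network plus diagnostics."""

    chambers: list
    isolated_unbiased: frozenset
    n_unbiased: int
    conventions: dict = field(default_factory=lambda: dict(CONVENTIONS))

    @property
    def eta(self) -> float:
        if self.n_unbiased == 0:
            return 0.0
        return sum(c.size for c in self.chambers) / self.n_unbiased


def find_echo_chambers(network: Network) -> list[EchoChamber]:
    """Detect all (disjoint, maximal) echo chambers of a network.

    Candidate chambers are the connected components of the subgraph induced
    on unbiased nodes (closure forces a chamber to be a full component: a
    member with an unbiased neighbour outside the set would violate the
    enclosure condition). A component qualifies if it has >= 2 members, a
    non-empty biased boundary, and comprises at most half of the unbiased
    population (the bulk of unbiased society is not an echo chamber).
    """
    return echo_report(network).chambers


def echo_report(network: Network) -> EchoReport:
    biased = network.biased
    unbiased = network.unbiased
    g = network.graph
    sub = g.subgraph(unbiased)
    max_size = CONVENTIONS["max_fraction_of_unbiased"] * len(unbiased)
    chambers = []
    isolated = set()
    for comp in nx.connected_components(sub):
        if len(comp) == 1:
            (node,) = comp
            if g.degree(node) > 0 and all(nb in biased for nb in g.neighbors(node)):
                isolated.add(node)
            continue
        if len(comp) > max_size:
            continue
        boundary = {
            nb for node in comp for nb in g.neighbors(node) if nb in biased
        }
        if boundary:
            chambers.append(
                EchoChamber(members=frozenset(comp), boundary=frozenset(boundary))
            )
    chambers.sort(key=lambda c: sorted(c.members))
    return EchoReport(
        chambers=chambers,
        isolated_unbiased=frozenset(isolated),
        n_unbiased=len(unbiased),
    )


def chamber_fraction(network: Network) -> float:
    """η_C: fraction of unbiased agents enclosed in echo chambers (0 if U empty)."""
    return echo_report(network).eta


def attach_mixes(chamber: EchoChamber, steady_state: SteadyState) -> EchoChamber:
    """Fill in the realized mean mixes of members and boundary."""
    x = steady_state.x_star
    members = sorted(chamber.members)
    boundary = sorted(chamber.boundary)
    if max(members + boundary) >= len(x):
        raise ValueError("steady state does not cover the chamber's nodes")
    chamber.x_members = float(np.mean(x[members]))
    chamber.x_boundary = float(np.mean(x[boundary]))
    return chamber


def permeability_residual(
    chamber: EchoChamber,
    steady_state: SteadyState,
    q: float,
    x_u_global: float,
) -> float:
    """Residual x_C* - (q x_∂C* + (1-q) x_U*) of the permeability relation.

    Uses the realized steady-state mixes of the chamber members and of its
    biased boundary agents; a small magnitude means the chamber's information
    content is the q-weighted blend of its gatekeepers and the wider network.
    """
    attach_mixes(chamber, steady_state)
    return chamber.x_members - (q * chamber.x_boundary + (1.0 - q) * x_u_global)


def brute_force_chambers(network: Network) -> list[frozenset]:
    """Reference detector: enumerate all vertex subsets (graphs <= ~16 nodes).

    Checks every subset of the unbiased nodes against the chamber definition
    (enclosure, internal contact, connectivity, and the conventions above)
    and keeps the maximal qualifying sets. Exponential; for validation only.
    """
    g = network.graph
    biased = network.biased
    unbiased = sorted(network.unbiased)
    if len(unbiased) > 16:
        raise ValueError("brute-force enumeration is limited to <= 16 unbiased nodes")
    max_size = CONVENTIONS["max_fraction_of_unbiased"] * len(unbiased)
    qualifying = []
    for r in range(CONVENTIONS["min_size"], len(unbiased) + 1):
        if r > max_size:
            break
        for subset in combinations(unbiased, r):
            cset = set(subset)
            ok = True
            boundary = set()
            for node in cset:
                nbrs = set(g.neighbors(node))
                if not nbrs <= (biased | cset):  # enclosure
                    ok = False
                    break
                if not nbrs & cset:  # internal contact
                    ok = False
                    break
                boundary |= nbrs & biased
            if not ok or not boundary:
                continue
            if not nx.is_connected(g.subgraph(cset)):
                continue
            qualifying.append(frozenset(cset))
    maximal = [
        c for c in qualifying if not any(c < other for other in qualifying)
    ]
    return sorted(set(maximal), key=sorted)
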