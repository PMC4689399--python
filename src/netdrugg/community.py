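"""Community detection and community-derived node features.

Two algorithms are run on the interactome: short-random-walk agglomeration
(walktrap, walk length 4, flat cut at maximal Newman-Girvan modularity) and
Potts-model simulated annealing (spin glass, 50 spins as the maximum
community count; stochastic, always seeded).  From a partition each node
gets its community id, community size, and *vertex modularity* -- the
fraction of its neighbours assigned to its own community.  A low vertex
modularity marks an inter-community communicator.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import pandas as pd

from .network_io import InteractionGraph

__all__ = [
    "CommunityPartition",
    "walktrap",
    "spinglass",
    "vertex_modularity",
    "community_features",
]


@dataclass
class CommunityPartition:
    """A flat node partition produced by one community algorithm."""

    algorithm: str
    assignment: dict[str, int]
    parameters: dict = field(default_factory=dict)

    def community_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for c in self.assignment.values():
            sizes[c] = sizes.get(c, 0) + 1
        return sizes

    def members(self, community: int) -> list[str]:
        return [v for v, c in self.assignment.items() if c == community]


def _relabel_contiguous(membership: list[int]) -> list[int]:
    """Relabel community ids to 0..k-1 in order of first appearance."""
    seen: dict[int, int] = {}
    out = []
    for c in membership:
        if c not in seen:
            seen[c] = len(seen)
        out.append(seen[c])
    return out


def walktrap(g: InteractionGraph, t: int = 4) -> CommunityPartition:
    """Random-walk agglomerative communities; deterministic for fixed input.

    Merges are driven by ``t``-step random-walk distances; the returned flat
    partition is the merge-tree cut maximizing modularity.
    """
    if t < 1:
        raise ValueError("walk length t must be >= 1")
    dendro = g.graph.community_walktrap(steps=t)
    clustering = dendro.as_clustering()  # cut at maximal modularity
    membership = _relabel_contiguous(clustering.membership)
    return CommunityPartition(
        algorithm="walktrap",
        assignment=dict(zip(g.names, membership)),
        parameters={"t": t},
    )


def spinglass(g: InteractionGraph, spins: int = 50, seed: int = 42) -> CommunityPartition:
    """Spin-glass (Potts model) communities via simulated annealing.

    ``spins`` caps the number of communities; gamma = 1; the annealing
    schedule runs from temperature 1 to 0.01 with cooling factor 0.99.  The
    seed is recorded in the partition parameters.
    """
    if spins < 2:
        raise ValueError("spins must be >= 2")
    random.seed(seed)  # python-igraph draws randomness from the random module
    clustering = g.graph.community_spinglass(
        spins=spins, gamma=1.0, start_temp=1.0, stop_temp=0.01, cool_fact=0.99,
    )
    membership = _relabel_contiguous(clustering.membership)
    n_comm = len(set(membership))
    if n_comm > spins:
        raise AssertionError("spin-glass returned more communities than spins")
    return CommunityPartition(
        algorithm="spinglass",
        assignment=dict(zip(g.names, membership)),
        parameters={"spins": spins, "seed": seed},
    )


def vertex_modularity(g: InteractionGraph, p: CommunityPartition, node: str) -> float:
    """Fraction of a node's neighbours that share its community (VM in [0,1])."""
    nbrs = g.neighbors(node)
    if not nbrs:
        raise ValueError(f"vertex modularity undefined for isolated node {node!r}")
    own = p.assignment[node]
    return sum(1 for u in nbrs if p.assignment[u] == own) / len(nbrs)


def community_features(g: InteractionGraph, partitions: list[CommunityPartition]) -> pd.DataFrame:
    """Feature block: per algorithm, community id / size / vertex modularity.

    Columns are named ``comm.<algorithm>.<metric>``.
    """
    out = pd.DataFrame(index=g.names)
    for p in partitions:
        missing = [v for v in g.names if v not in p.assignment]
        if missing:
            raise KeyError(f"partition {p.algorithm!r} missing nodes, e.g. {missing[0]!r}")
        sizes = p.community_sizes()
        out[f"comm.{p.algorithm}.community_id"] = [p.assignment[v] for v in g.names]
        out[f"comm.{p.algorithm}.community_size"] = [sizes[p.assignment[v]] for v in g.names]
        out[f"comm.{p.algorithm}.vertex_modularity"] = [
            vertex_modularity(g, p, v) for v in g.names
        ]
    return out
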