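"""Graphlet degree vectors: per-node counts of automorphism orbits 0-72.

A *graphlet* is a small connected induced subgraph; on 2-5 nodes there are
exactly 30 of them (G0-G29), whose node positions fall into 73 automorphism
*orbits* (0-72).  A node's vector of orbit participation counts (its graphlet
degree vector, GDV) is a rich local-topology descriptor: orbit 0 is plain
degree, orbit 3 the triangle count, orbits 65-72 participation in the
densest five-node subgraphs.

Two counters are provided: an efficient enumerator of connected induced
vertex sets (ESU traversal compiled with numba, classifying each set through
a precomputed labelled-subgraph lookup table) and a naive brute-force
enumerator used as an independent oracle on small graphs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd
from numba import njit

from .network_io import InteractionGraph

logger = logging.getLogger(__name__)

__all__ = [
    "GraphletAtlas",
    "build_atlas",
    "atlas_reference_text",
    "count_orbits",
    "count_orbits_bruteforce",
    "graphlet_features",
    "N_GRAPHLETS",
    "N_ORBITS",
]

N_GRAPHLETS = 30
N_ORBITS = 73

# Canonical graphlet table, G0 (single edge) .. G29 (K5), ordered by node
# count then increasing density following the standard numbering (edge,
# 3-path, triangle, ..., K5-minus-an-edge, K5).
GRAPHLET_EDGES: list[list[tuple[int, int]]] = [
    # 2 nodes
    [(0, 1)],                                                        # G0 edge
    # 3 nodes
    [(0, 1), (1, 2)],                                                # G1 path P3
    [(0, 1), (1, 2), (0, 2)],                                        # G2 triangle
    # 4 nodes
    [(0, 1), (1, 2), (2, 3)],                                        # G3 path P4
    [(0, 1), (0, 2), (0, 3)],                                        # G4 claw K1,3
    [(0, 1), (1, 2), (2, 3), (3, 0)],                                # G5 cycle C4
    [(0, 1), (1, 2), (0, 2), (0, 3)],                                # G6 paw
    [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)],                        # G7 diamond
    [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)],                # G8 K4
    # 5 nodes
    [(0, 1), (1, 2), (2, 3), (3, 4)],                                # G9 path P5
    [(0, 1), (1, 2), (2, 3), (1, 4)],                                # G10 fork/chair
    [(0, 1), (0, 2), (0, 3), (0, 4)],                                # G11 star K1,4
    [(0, 1), (0, 2), (1, 2), (0, 3), (0, 4)],                        # G12 cricket
    [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4)],                        # G13 tadpole (triangle + 2-path)
    [(0, 1), (0, 2), (1, 2), (0, 3), (1, 4)],                        # G14 bull
    [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)],                        # G15 cycle C5
    [(0, 1), (1, 2), (2, 3), (3, 0), (0, 4)],                        # G16 pan (C4 + pendant)
    [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 4)],                # G17 diamond + pendant on deg-2
    [(0, 1), (0, 2), (1, 2), (0, 3), (0, 4), (3, 4)],                # G18 bowtie
    [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (0, 4)],                # G19 diamond + pendant on deg-3
    [(0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4)],                # G20 K2,3
    [(1, 2), (2, 3), (3, 4), (4, 1), (0, 1), (0, 2)],                # G21 house
    [(0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4), (0, 1)],        # G22 K2,3 + edge in 2-side
    [(0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4), (2, 3)],        # G23 K2,3 + edge in 3-side
    [(1, 2), (2, 3), (3, 4), (0, 1), (0, 2), (0, 3), (0, 4)],        # G24 gem (P4 + apex)
    [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3), (0, 4)],        # G25 K4 + pendant
    [(0, 3), (0, 4), (1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)],            # G26 K5 - 2 adjacent edges
    [(0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4), (2, 4), (3, 4)],            # G27 K5 - perfect matching pair
    [(0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)],    # G28 K5 - edge
    [(0, 1), (0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4), (2, 3), (2, 4),
     (3, 4)],                                                                    # G29 K5
]

# size of each graphlet (node count)
GRAPHLET_SIZES = [2, 3, 3, 4, 4, 4, 4, 4, 4] + [5] * 21


def _automorphism_orbits(k: int, edges: list[tuple[int, int]]) -> list[list[int]]:
    """Node orbits under the automorphism group, by brute-force permutation."""
    eset = {frozenset(e) for e in edges}
    orbit_of = list(range(k))
    for perm in itertools.permutations(range(k)):
        if {frozenset((perm[a], perm[b])) for a, b in eset} == eset:
            for v in range(k):
                a, b = orbit_of[v], orbit_of[perm[v]]
                if a != b:  # union
                    lo, hi = min(a, b), max(a, b)
                    orbit_of = [lo if x == hi else x for x in orbit_of]
    groups: dict[int, list[int]] = {}
    for v, o in enumerate(orbit_of):
        groups.setdefault(o, []).append(v)
    return list(groups.values())


def _refinement_key(k: int, edges: list[tuple[int, int]], v: int):
    """Deterministic node invariant: iterated neighbour-degree refinement.

    Orders orbits within a graphlet (pendant positions before hubs); it
    reproduces the anchored published orbit ids (path end < path middle,
    claw leaf < claw centre, ...).
    """
    adj: list[list[int]] = [[] for _ in range(k)]
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    labels: list = [len(adj[u]) for u in range(k)]
    history = [labels[v]]
    for _ in range(3):
        labels = [(labels[u], tuple(sorted(labels[w] for w in adj[u]))) for u in range(k)]
        history.append(labels[v])
    return tuple(history)


@dataclass(frozen=True)
class GraphletAtlas:
    """The 30 canonical 2-5-node graphlets and their 73 node orbits.

    ``orbit_of[g][v]`` is the global orbit id (0-72) of node ``v`` in
    graphlet ``g``; ``orbit_graphlet[o]`` maps an orbit back to its parent
    graphlet; ``orbit_multiplicity[o]`` is the number of nodes of the
    graphlet sitting at that orbit.
    """

    edges: tuple[tuple[tuple[int, int], ...], ...]
    sizes: tuple[int, ...]
    orbit_of: tuple[tuple[int, ...], ...]
    orbit_graphlet: tuple[int, ...]
    orbit_multiplicity: tuple[int, ...]

    @property
    def n_graphlets(self) -> int:
        return len(self.edges)

    @property
    def n_orbits(self) -> int:
        return len(self.orbit_graphlet)

    def orbits_of_graphlet(self, g: int) -> list[int]:
        return sorted(set(self.orbit_of[g]))


@lru_cache(maxsize=1)
def build_atlas() -> GraphletAtlas:
    """Construct the atlas: orbits from automorphism groups, numbered 0-72.

    Orbits are numbered sequentially G0 through G29; within a graphlet,
    orbits are ordered by the ascending neighbour-degree refinement key of
    a representative node, so that orbit 0 is the edge end, orbit 1/2 the
    3-path end/middle, orbit 3 the triangle, and orbit 72 a K5 node.
    """
    orbit_of: list[tuple[int, ...]] = []
    orbit_graphlet: list[int] = []
    orbit_multiplicity: list[int] = []
    next_orbit = 0
    for gi, edges in enumerate(GRAPHLET_EDGES):
        k = GRAPHLET_SIZES[gi]
        groups = _automorphism_orbits(k, edges)
        keys = [_refinement_key(k, edges, grp[0]) for grp in groups]
        assert len(set(keys)) == len(groups), f"orbit key collision in G{gi}"
        order = sorted(range(len(groups)), key=lambda i: keys[i])
        assign = [0] * k
        for rank, i in enumerate(order):
            for v in groups[i]:
                assign[v] = next_orbit + rank
            orbit_graphlet.append(gi)
            orbit_multiplicity.append(len(groups[i]))
        next_orbit += len(groups)
        orbit_of.append(tuple(assign))
    atlas = GraphletAtlas(
        edges=tuple(tuple(e) for e in GRAPHLET_EDGES),
        sizes=tuple(GRAPHLET_SIZES),
        orbit_of=tuple(orbit_of),
        orbit_graphlet=tuple(orbit_graphlet),
        orbit_multiplicity=tuple(orbit_multiplicity),
    )
    assert atlas.n_graphlets == N_GRAPHLETS
    assert atlas.n_orbits == N_ORBITS
    return atlas


def atlas_reference_text() -> str:
    """Human-readable dump of the atlas: edge lists and the orbit table."""
    atlas = build_atlas()
    lines = ["# graphlet atlas: 30 graphlets on 2-5 nodes, 73 node orbits",
             "# graphlet <id> nodes=<k> edges=<edge list> orbits=<orbit id per node>"]
    for gi in range(atlas.n_graphlets):
        es = " ".join(f"{a}-{b}" for a, b in atlas.edges[gi])
        orbs = " ".join(str(o) for o in atlas.orbit_of[gi])
        lines.append(f"graphlet G{gi} nodes={atlas.sizes[gi]} edges=[{es}] orbits=[{orbs}]")
    lines.append("# orbit <id> graphlet=<parent> multiplicity=<nodes at orbit>")
    for o in range(atlas.n_orbits):
        lines.append(
            f"orbit {o} graphlet=G{atlas.orbit_graphlet[o]} multiplicity={atlas.orbit_multiplicity[o]}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# labelled-subgraph lookup tables
# ---------------------------------------------------------------------------
# Pairs of a k-node vertex tuple are bit-indexed (0,1),(0,2),(1,2),(0,3),...:
# bit(i,j) = j*(j-1)/2 + i for i<j, so smaller-k masks are prefixes.


def _pair_bit(i: int, j: int) -> int:
    if i > j:
        i, j = j, i
    return j * (j - 1) // 2 + i


@lru_cache(maxsize=1)
def _orbit_tables() -> dict[int, np.ndarray]:
    """For each k=2..5: table[mask, pos] = orbit id (or -1 if disconnected)."""
    atlas = build_atlas()
    by_size: dict[int, list[int]] = {}
    for gi, k in enumerate(atlas.sizes):
        by_size.setdefault(k, []).append(gi)
    tables: dict[int, np.ndarray] = {}
    for k in range(2, 6):
        nbits = k * (k - 1) // 2
        tab = np.full((1 << nbits, k), -1, dtype=np.int8)
        pairs = list(itertools.combinations(range(k), 2))
        for mask in range(1 << nbits):
            edges = [p for p in pairs if mask >> _pair_bit(*p) & 1]
            g = nx.Graph(edges)
            g.add_nodes_from(range(k))
            if not nx.is_connected(g):
                continue
            eset = {frozenset(e) for e in edges}
            for gi in by_size[k]:
                if len(atlas.edges[gi]) != len(eset):
                    continue
                target = {frozenset(e) for e in atlas.edges[gi]}
                for perm in itertools.permutations(range(k)):
                    if {frozenset((perm[a], perm[b])) for a, b in eset} == target:
                        for v in range(k):
                            tab[mask, v] = atlas.orbit_of[gi][perm[v]]
                        break
                if tab[mask, 0] >= 0:
                    break
            assert tab[mask, 0] >= 0, f"unclassified connected mask {mask} at k={k}"
        tables[k] = tab
    return tables


# ---------------------------------------------------------------------------
# efficient counter: ESU enumeration of connected induced vertex sets
# ---------------------------------------------------------------------------


@njit(cache=True)
def _has_edge(indptr, indices, u, v):
    lo = indptr[u]
    hi = indptr[u + 1]
    while lo < hi:
        mid = (lo + hi) // 2
        x = indices[mid]
        if x == v:
            return True
        if x < v:
            lo = mid + 1
        else:
            hi = mid
    return False


@njit(cache=True)
def _esu_count(n, indptr, indices, tab3, tab4, tab5, counts):
    """Enumerate every connected induced vertex set of size 2-5 exactly once
    (ESU traversal) and credit each member node at its orbit."""
    sub = np.empty(5, np.int64)
    masks = np.empty(5, np.int64)
    ext = np.empty((5, n), np.int64)
    ext_len = np.empty(5, np.int64)
    ext_ptr = np.empty(5, np.int64)
    undo = np.empty((5, n), np.int64)
    undo_len = np.empty(5, np.int64)
    mark = np.zeros(n, np.uint8)

    for root in range(n):
        deg0 = indptr[root + 1] - indptr[root]
        if deg0 == 0:
            continue
        sub[0] = root
        masks[0] = 0
        mark[root] = 1
        ne = 0
        for p in range(indptr[root], indptr[root + 1]):
            u = indices[p]
            mark[u] = 1
            if u > root:
                ext[0, ne] = u
                ne += 1
        ext_len[0] = ne
        ext_ptr[0] = 0
        d = 0
        while d >= 0:
            if ext_ptr[d] < ext_len[d]:
                w = ext[d, ext_ptr[d]]
                ext_ptr[d] += 1
                s = d + 1  # index of w in sub; subgraph size is s+1
                sub[s] = w
                base = s * (s - 1) // 2
                m = masks[s - 1]
                for t in range(s):
                    if _has_edge(indptr, indices, sub[t], w):
                        m |= 1 << (base + t)
                masks[s] = m
                size = s + 1
                # credit every member of the current set at its orbit
                if size == 2:
                    counts[sub[0], 0] += 1
                    counts[sub[1], 0] += 1
                elif size == 3:
                    for t in range(3):
                        counts[sub[t], tab3[m, t]] += 1
                elif size == 4:
                    for t in range(4):
                        counts[sub[t], tab4[m, t]] += 1
                else:
                    for t in range(5):
                        counts[sub[t], tab5[m, t]] += 1
                if size < 5:
                    # extension for the child level: remaining siblings plus
                    # exclusive neighbours of w (> root, not in sub or N(sub))
                    ne = 0
                    for q in range(ext_ptr[d], ext_len[d]):
                        ext[s, ne] = ext[d, q]
                        ne += 1
                    nu = 0
                    for p in range(indptr[w], indptr[w + 1]):
                        u = indices[p]
                        if mark[u] == 0:
                            mark[u] = 1
                            undo[s, nu] = u
                            nu += 1
                            if u > root:
                                ext[s, ne] = u
                                ne += 1
                    undo_len[s] = nu
                    ext_len[s] = ne
                    ext_ptr[s] = 0
                    d = s
            else:
                # level exhausted: undo its marks and backtrack
                if d > 0:
                    for q in range(undo_len[d]):
                        mark[undo[d, q]] = 0
                d -= 1
        # clear root-level marks
        mark[root] = 0
        for p in range(indptr[root], indptr[root + 1]):
            mark[indices[p]] = 0


def _csr(g: InteractionGraph) -> tuple[np.ndarray, np.ndarray]:
    n = g.n
    adj = [np.array(sorted(g.graph.neighbors(v)), dtype=np.int64) for v in range(n)]
    indptr = np.zeros(n + 1, dtype=np.int64)
    for v in range(n):
        indptr[v + 1] = indptr[v] + len(adj[v])
    indices = np.concatenate(adj) if n else np.empty(0, dtype=np.int64)
    return indptr, indices.astype(np.int64)


def count_orbits(g: InteractionGraph) -> pd.DataFrame:
    """Graphlet degree vectors for every node: a (node x 73) count table.

    Counts are over *induced* connected subgraphs on 2-5 nodes; each
    subgraph instance credits every one of its nodes once, at the orbit the
    node occupies.  Column ``o0`` equals the node degree.
    """
    if g.n > 100_000:
        logger.warning("count_orbits: %d nodes; enumeration may be very slow", g.n)
    tables = _orbit_tables()
    counts = np.zeros((g.n, N_ORBITS), dtype=np.int64)
    indptr, indices = _csr(g)
    _esu_count(g.n, indptr, indices, tables[3], tables[4], tables[5], counts)
    return pd.DataFrame(counts, index=g.names, columns=[f"o{k}" for k in range(N_ORBITS)])


def _match_atlas(k: int, adj: list[set[int]], candidates, atlas) -> tuple[int, tuple[int, ...]]:
    """Find (graphlet id, node->orbit-position mapping) for a small graph by
    degree-filtered permutation search (independent of the lookup tables)."""
    degseq = tuple(sorted(len(a) for a in adj))
    m = sum(len(a) for a in adj) // 2
    for gi in candidates:
        g_edges = atlas.edges[gi]
        if len(g_edges) != m:
            continue
        g_adj: list[set[int]] = [set() for _ in range(k)]
        for a, b in g_edges:
            g_adj[a].add(b)
            g_adj[b].add(a)
        if tuple(sorted(len(a) for a in g_adj)) != degseq:
            continue
        for perm in itertools.permutations(range(k)):
            ok = True
            for v in range(k):
                if len(adj[v]) != len(g_adj[perm[v]]):
                    ok = False
                    break
                if any(perm[u] not in g_adj[perm[v]] for u in adj[v]):
                    ok = False
                    break
            if ok:
                return gi, perm
    raise AssertionError("connected subgraph not matched in atlas")


def count_orbits_bruteforce(g: InteractionGraph, guard: int = 40) -> pd.DataFrame:
    """Oracle counter: direct enumeration of all 2-5 vertex subsets.

    Each subset inducing a connected subgraph is classified by an explicit
    isomorphism search against the atlas, independently of the enumeration
    and lookup tables used by the efficient counter.  Refuses graphs above
    ``guard`` nodes.
    """
    if g.n > guard:
        raise ValueError(f"brute-force counter is guarded to n <= {guard} (got {g.n})")
    atlas = build_atlas()
    by_size: dict[int, list[int]] = {}
    for gi, k in enumerate(atlas.sizes):
        by_size.setdefault(k, []).append(gi)
    counts = np.zeros((g.n, N_ORBITS), dtype=np.int64)
    full_adj: list[set[int]] = [set(g.graph.neighbors(v)) for v in range(g.n)]
    for k in range(2, 6):
        for subset in itertools.combinations(range(g.n), k):
            pos = {v: i for i, v in enumerate(subset)}
            adj: list[set[int]] = [
                {pos[u] for u in full_adj[v] if u in pos} for v in subset
            ]
            # connectivity by BFS over the induced subgraph
            seen = {0}
            stack = [0]
            while stack:
                x = stack.pop()
                for y in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            if len(seen) < k:
                continue
            gi, perm = _match_atlas(k, adj, by_size[k], atlas)
            for i, v in enumerate(subset):
                counts[v, atlas.orbit_of[gi][perm[i]]] += 1
    return pd.DataFrame(counts, index=g.names, columns=[f"o{k}" for k in range(N_ORBITS)])


def graphlet_features(g: InteractionGraph, gdv: pd.DataFrame | None = None) -> pd.DataFrame:
    """Feature block: 73 orbit counts plus 30 per-graphlet totals.

    The per-graphlet total for a node is the sum of its counts over the
    orbits of that graphlet (its participation count in the graphlet,
    weighted by the number of positions it occupies).
    """
    atlas = build_atlas()
    if gdv is None:
        gdv = count_orbits(g)
    out = gdv.rename(columns=lambda c: f"orbit.{c}")
    for gi in range(atlas.n_graphlets):
        orbs = [f"orbit.o{o}" for o in atlas.orbits_of_graphlet(gi)]
        out[f"graphlet.G{gi}"] = out[orbs].sum(axis=1)
    return out
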