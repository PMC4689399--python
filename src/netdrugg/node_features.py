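"""Per-node topological descriptors of the interactome.

The topology block covers the classical centrality/cohesion suite (degree,
closeness, betweenness, eccentricity, PageRank, HITS hub/authority,
eigenvector centrality, clustering, coreness, neighbourhood-degree and
distance summaries), Burt's structural-holes constraint, articulation-point
membership, a pairwise disconnectivity index (the fraction of connected
ordered node pairs lost when the node is deleted), and the two leading
coordinates of a classical MDS embedding of Dice neighbour-sharing
distances (V1/V2).

All metrics are computed on the simple unweighted graph.  The registry of
columns is explicit (`TOPOLOGY_REGISTRY`) and configurable.
"""

from __future__ import annotations

import logging

import igraph as ig
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp

from .network_io import InteractionGraph

logger = logging.getLogger(__name__)

__all__ = [
    "TOPOLOGY_REGISTRY",
    "articulation_points",
    "burt_constraint",
    "disconnectivity_index",
    "centrality_suite",
    "dice_mds",
    "topology_features",
]

#: default metric registry of the topology block (31 columns + V1/V2).
TOPOLOGY_REGISTRY: tuple[str, ...] = (
    "degree",
    "is_articulation",
    "burt_constraint",
    "closeness",
    "betweenness",
    "eccentricity",
    "pagerank",
    "hub_score",
    "authority_score",
    "eigenvector_centrality",
    "clustering_coefficient",
    "coreness",
    "disconnectivity",
    "harmonic_closeness",
    "mean_distance",
    "median_distance",
    "max_neighbor_degree",
    "min_neighbor_degree",
    "mean_neighbor_degree",
    "sd_neighbor_degree",
    "neighborhood_size_2",
    "neighborhood_size_3",
    "triangles",
    "squares",
    "degree_centrality",
    "load_centrality",
    "subgraph_centrality",
    "local_efficiency",
    "avg_neighbor_clustering",
    "within_module_z",  # degree z-score among nodes of similar coreness shell
    "bridge_edges",     # number of incident bridges
    "mds_v1",
    "mds_v2",
)


def articulation_points(g: InteractionGraph) -> set[str]:
    """Nodes whose removal disconnects the graph (DFS biconnected components)."""
    return {g.names[v] for v in g.graph.articulation_points()}


def burt_constraint(g: InteractionGraph, node: str | None = None):
    """Burt's structural-holes constraint.

    ``c(i) = sum_j (p_ij + sum_q p_iq p_qj)^2`` over direct contacts ``j``,
    with ``p_xy = 1/k_x`` on an unweighted graph: how concentrated a node's
    connections are within one mutually redundant neighbourhood (1.125 for a
    triangle node, 1/3 for the centre of a 3-star).
    """
    def one(v: int) -> float:
        nbrs = g.graph.neighbors(v)
        k = len(nbrs)
        if k == 0:
            raise ValueError("constraint undefined for an isolated node")
        p_i = 1.0 / k
        total = 0.0
        nbr_set = set(nbrs)
        for j in nbrs:
            indirect = 0.0
            for q in g.graph.neighbors(v):
                if q == j:
                    continue
                if g.graph.are_adjacent(q, j):
                    indirect += p_i / g.graph.degree(q)
            total += (p_i + indirect) ** 2
        return total

    if node is not None:
        return one(g.index[node])
    return {name: one(v) for v, name in enumerate(g.names)}


def disconnectivity_index(g: InteractionGraph, node: str | None = None):
    """Pairwise disconnectivity index Dis(v) in [0, 1].

    ``Dis(v) = (N0 - N_minus_v) / N0`` where ``N0 = n(n-1)`` is the number
    of ordered connected node pairs of the (connected) graph and
    ``N_minus_v`` the ordered connected pairs remaining after deleting v.
    A non-articulation node always scores exactly ``2/n`` (it only loses
    its own pairs); articulation points score strictly more.
    """
    n = g.n
    if n < 3:
        raise ValueError("disconnectivity index needs n >= 3")
    n0 = n * (n - 1)

    def one(v: int) -> float:
        h = g.graph.copy()
        h.delete_vertices([v])
        remaining = sum(len(c) * (len(c) - 1) for c in h.connected_components())
        return (n0 - remaining) / n0

    if node is not None:
        return one(g.index[node])
    return {name: one(v) for v, name in enumerate(g.names)}


def _adjacency(g: InteractionGraph) -> sp.csr_matrix:
    n = g.n
    rows, cols = [], []
    for e in g.graph.es:
        rows += [e.source, e.target]
        cols += [e.target, e.source]
    return sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))


def _power_iteration(matvec, n: int, tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """Leading eigenvector by power iteration from a uniform start,
    rescaled to max 1 (deterministic for a fixed operator)."""
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        y = np.asarray(matvec(x)).ravel()
        norm = np.abs(y).max()
        if norm == 0:
            return np.zeros(n)
        y = y / norm
        if np.abs(y - x).max() < tol:
            x = y
            break
        x = y
    return np.clip(x / np.abs(x).max(), 0.0, 1.0)


def centrality_suite(g: InteractionGraph) -> pd.DataFrame:
    """The igraph-backed centrality/cohesion metrics, one row per node.

    Closeness is normalized ((n-1)/sum of distances); betweenness is the
    raw shortest-path count; PageRank uses damping 0.85; HITS and
    eigenvector scores are scaled to max 1; clustering is 0 for degree < 2.
    Deterministic for a fixed graph.
    """
    gr = g.graph
    n = g.n
    deg = np.asarray(gr.degree(), dtype=float)
    out = pd.DataFrame(index=g.names)
    out["degree"] = deg
    aps = set(gr.articulation_points())
    out["is_articulation"] = [float(v in aps) for v in range(n)]
    out["closeness"] = gr.closeness(normalized=True)
    out["betweenness"] = gr.betweenness(directed=False)
    out["eccentricity"] = gr.eccentricity()
    out["pagerank"] = gr.pagerank(damping=0.85)
    # eigenvector-flavoured scores via deterministic power iteration
    # (uniform start, tolerance 1e-10) so reruns are bit-identical
    A = _adjacency(g)
    ev = _power_iteration(lambda x: A @ x + x, n)  # shift by I: no bipartite oscillation
    hits = _power_iteration(lambda x: A @ (A @ x), n)  # A^2: hub == authority, undirected
    out["hub_score"] = hits
    out["authority_score"] = hits
    out["eigenvector_centrality"] = ev
    out["clustering_coefficient"] = gr.transitivity_local_undirected(mode="zero")
    out["coreness"] = gr.coreness()

    # distance summaries
    dists = np.asarray(gr.distances(), dtype=float)
    np.fill_diagonal(dists, np.nan)
    with np.errstate(invalid="ignore"):
        out["harmonic_closeness"] = np.nansum(1.0 / dists, axis=1) / (n - 1)
        out["mean_distance"] = np.nanmean(dists, axis=1)
        out["median_distance"] = np.nanmedian(dists, axis=1)
    out["neighborhood_size_2"] = [len(x) - 1 for x in gr.neighborhood(order=2)]
    out["neighborhood_size_3"] = [len(x) - 1 for x in gr.neighborhood(order=3)]

    # neighbour-degree summaries
    maxnd, minnd, meannd, sdnd, nclust = [], [], [], [], []
    clust = np.asarray(out["clustering_coefficient"], dtype=float)
    for v in range(n):
        nd = deg[gr.neighbors(v)]
        maxnd.append(nd.max())
        minnd.append(nd.min())
        meannd.append(nd.mean())
        sdnd.append(nd.std())
        nclust.append(clust[gr.neighbors(v)].mean())
    out["max_neighbor_degree"] = maxnd
    out["min_neighbor_degree"] = minnd
    out["mean_neighbor_degree"] = meannd
    out["sd_neighbor_degree"] = sdnd
    out["avg_neighbor_clustering"] = nclust

    # motif-flavoured counts
    A = np.asarray(_adjacency(g).todense(), dtype=float)
    A2 = A @ A
    A3 = A2 @ A
    out["triangles"] = np.diag(A3) / 2.0
    A4 = A3 @ A
    # closed 4-walks minus degenerate back-and-forth walks
    out["squares"] = (np.diag(A4) - deg**2 - (A2 * (1 - np.eye(n))).sum(axis=1)) / 2.0
    out["degree_centrality"] = deg / (n - 1)
    out["load_centrality"] = out["betweenness"] / ((n - 1) * (n - 2) / 2.0) if n > 2 else 0.0
    # communicability via eigendecomposition, scaled by the spectral radius
    w, vecs = np.linalg.eigh(A)
    w_scaled = w / max(abs(w).max(), 1.0)
    out["subgraph_centrality"] = (vecs**2 @ np.exp(w_scaled))
    # local efficiency: mean inverse distance within the open neighbourhood
    leff = []
    for v in range(n):
        nb = gr.neighbors(v)
        if len(nb) < 2:
            leff.append(0.0)
            continue
        sub = gr.induced_subgraph(nb)
        d = np.asarray(sub.distances(), dtype=float)
        iu = np.triu_indices(len(nb), k=1)
        inv = 1.0 / d[iu]
        inv[~np.isfinite(inv)] = 0.0
        leff.append(2.0 * inv.sum() / (len(nb) * (len(nb) - 1)))
    out["local_efficiency"] = leff

    # degree z-score within the node's coreness shell
    core = np.asarray(out["coreness"], dtype=float)
    z = np.zeros(n)
    for shell in np.unique(core):
        m = core == shell
        mu, sd = deg[m].mean(), deg[m].std()
        z[m] = (deg[m] - mu) / sd if sd > 0 else 0.0
    out["within_module_z"] = z

    bridges = set()
    for e in g.graph.bridges():
        bridges.add(e)
    bcount = np.zeros(n)
    for eid in bridges:
        e = gr.es[eid]
        bcount[e.source] += 1
        bcount[e.target] += 1
    out["bridge_edges"] = bcount
    return out


def dice_similarity_matrix(g: InteractionGraph) -> np.ndarray:
    """Pairwise Dice neighbour-sharing similarity, s(u,u) = 1."""
    n = g.n
    rows, cols = [], []
    for e in g.graph.es:
        rows += [e.source, e.target]
        cols += [e.target, e.source]
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    common = np.asarray((A @ A.T).todense(), dtype=float)
    deg = np.asarray(g.graph.degree(), dtype=float)
    denom = deg[:, None] + deg[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > 0, 2.0 * common / denom, 0.0)
    np.fill_diagonal(s, 1.0)
    return s


def dice_mds(g: InteractionGraph) -> pd.DataFrame:
    """V1/V2: leading classical-MDS coordinates of Dice distances.

    Dice similarity ``s(u,v) = 2|N(u) n N(v)| / (|N(u)|+|N(v)|)`` is turned
    into the distance ``1 - s`` and embedded with Torgerson double
    centering; V1/V2 are the two top-eigenvalue coordinates.  Classical MDS
    is defined only up to reflection, so each axis is flipped, if needed,
    so that the lexicographically smallest node name among those with
    maximal |coordinate| gets a positive value.
    """
    if g.n < 3:
        raise ValueError("dice_mds needs n >= 3")
    d = 1.0 - dice_similarity_matrix(g)
    n = g.n
    d2 = d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    vals, vecs = scipy.linalg.eigh(b, subset_by_index=(n - 2, n - 1))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = np.zeros((n, 2))
    if vals[0] <= 1e-12:
        logger.warning("dice_mds: degenerate distance matrix, coordinates set to 0")
        return pd.DataFrame(coords, index=g.names, columns=["mds_v1", "mds_v2"])
    for k in range(2):
        if vals[k] > 1e-12:
            coords[:, k] = vecs[:, k] * np.sqrt(vals[k])
    # reflection fix
    names = np.asarray(g.names)
    for k in range(2):
        col = coords[:, k]
        amax = np.abs(col).max()
        if amax <= 0:
            continue
        cands = np.isclose(np.abs(col), amax)
        pick = np.argsort(names[cands])[0]
        if col[cands][pick] < 0:
            coords[:, k] = -col
    return pd.DataFrame(coords, index=g.names, columns=["mds_v1", "mds_v2"])


def topology_features(g: InteractionGraph, registry: tuple[str, ...] = TOPOLOGY_REGISTRY) -> pd.DataFrame:
    """Assemble the full topology feature block, columns ``topo.<metric>``.

    Raises if any metric produces a non-finite value.
    """
    base = centrality_suite(g)
    base["burt_constraint"] = pd.Series(burt_constraint(g))
    base["disconnectivity"] = pd.Series(disconnectivity_index(g))
    mds = dice_mds(g)
    base["mds_v1"] = mds["mds_v1"]
    base["mds_v2"] = mds["mds_v2"]
    missing = [m for m in registry if m not in base.columns]
    if missing:
        raise KeyError(f"unknown registry metrics: {missing}")
    out = base[list(registry)].copy()
    bad = ~np.isfinite(out.to_numpy(dtype=float))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FloatingPointError(
            f"non-finite value for node {out.index[i]!r}, metric {out.columns[j]!r}"
        )
    out.columns = [f"topo.{c}" for c in out.columns]
    return out
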