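"""Parsing of interaction data and construction of the cleaned interactome graph.

The whole pipeline operates on a *simple, undirected, connected* graph over
protein identifiers.  Raw interaction records (edge lists or PSI-MITAB rows)
are cleaned in a fixed order -- ambiguous complex-expansion records, self
loops, duplicate/reciprocal pairs, and finally everything outside the largest
connected component -- and the count removed at every step is kept in a
provenance log so the bookkeeping can be audited.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import igraph as ig

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "InteractionGraph",
    "ParseError",
    "read_edge_list",
    "read_psimitab",
    "build_graph",
    "write_graph",
]


class ParseError(ValueError):
    """Raised for malformed interaction input files."""


@dataclass(frozen=True)
class InteractionRecord:
    """One reported binary interaction between two proteins.

    ``(a, b)`` and ``(b, a)`` are semantically the same interaction; the
    parser preserves the reported order and :func:`build_graph` collapses
    them.  ``ambiguous_complex_expansion`` marks records derived from
    expanding an n-ary complex into binary pairs (spoke/matrix expansion),
    which can optionally be discarded.
    """

    id_a: str
    id_b: str
    source: str = ""
    ambiguous_complex_expansion: bool = False

    def __post_init__(self) -> None:
        if not self.id_a or not self.id_b:
            raise ValueError("interaction identifiers must be non-empty")


@dataclass
class InteractionGraph:
    """Simple undirected connected graph over protein identifiers.

    ``names`` is sorted lexicographically so that vertex indexing -- and with
    it every downstream computation -- is deterministic for a given edge set.
    """

    names: list[str]
    graph: ig.Graph
    provenance: dict = field(default_factory=dict)

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return self.graph.vcount()

    @property
    def m(self) -> int:
        return self.graph.ecount()

    @property
    def index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.names)}

    def degree(self) -> dict[str, int]:
        return dict(zip(self.names, self.graph.degree()))

    def neighbors(self, name: str) -> list[str]:
        i = self.index[name]
        return [self.names[j] for j in self.graph.neighbors(i)]

    def edge_set(self) -> set[tuple[str, str]]:
        out = set()
        for e in self.graph.es:
            a, b = self.names[e.source], self.names[e.target]
            out.add((a, b) if a <= b else (b, a))
        return out

    @classmethod
    def from_edges(cls, edges, provenance: dict | None = None) -> "InteractionGraph":
        """Build from an iterable of (id_a, id_b) name pairs (assumed clean)."""
        edges = [(str(a), str(b)) for a, b in edges]
        names = sorted({x for e in edges for x in e})
        idx = {name: i for i, name in enumerate(names)}
        g = ig.Graph(n=len(names), edges=[(idx[a], idx[b]) for a, b in edges])
        g.vs["name"] = names
        return cls(names=names, graph=g, provenance=provenance or {})


def read_edge_list(path, delimiter: str | None = None) -> list[InteractionRecord]:
    """Parse a 2+-column delimited edge list into interaction records.

    Lines starting with ``#`` are skipped.  ``delimiter=None`` splits on any
    whitespace.  The parser does not clean: self loops and duplicates survive
    until :func:`build_graph`.
    """
    records: list[InteractionRecord] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                skipped += 1
                continue
            parts = line.split(delimiter)
            parts = [p for p in parts if p != ""]
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected >=2 fields, got {len(parts)}")
            records.append(InteractionRecord(parts[0], parts[1], source=str(path)))
    if not records:
        raise ParseError(f"{path}: no interaction records found")
    logger.info("read_edge_list: %d records parsed, %d lines skipped", len(records), skipped)
    return records


def _mitab_id(field_: str, namespace: str) -> str | None:
    """Extract an accession with the given namespace from a MITAB id field."""
    for token in field_.split("|"):
        if ":" in token:
            ns, acc = token.split(":", 1)
            if ns.strip().lower() == namespace:
                return acc.strip().strip('"')
    return None


def read_psimitab(path, namespace: str = "uniprotkb") -> list[InteractionRecord]:
    """Parse a PSI-MITAB 2.5/2.7 file into interaction records.

    Identifiers come from columns 1-2, preferring ``namespace`` accessions
    (searching the alternative-id columns 3-4 as a fallback); rows whose
    expansion column (MITAB 2.7, column 16) marks spoke or matrix expansion
    are flagged ``ambiguous_complex_expansion``.
    """
    records: list[InteractionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 15:
                raise ParseError(f"{path}: line {lineno}: MITAB requires >=15 columns, got {len(cols)}")
            ids = []
            for primary, alt in ((cols[0], cols[2]), (cols[1], cols[3])):
                acc = _mitab_id(primary, namespace) or _mitab_id(alt, namespace)
                if acc is None:
                    acc = primary.split("|")[0].strip()
                    logger.warning(
                        "read_psimitab: line %d: no %s accession, keeping raw id %r",
                        lineno, namespace, acc,
                    )
                ids.append(acc)
            expansion = cols[15].lower() if len(cols) > 15 else ""
            ambiguous = "spoke" in expansion or "matrix" in expansion
            records.append(
                InteractionRecord(ids[0], ids[1], source=str(path), ambiguous_complex_expansion=ambiguous)
            )
    if not records:
        raise ParseError(f"{path}: no interaction records found")
    return records


def build_graph(records: list[InteractionRecord], drop_ambiguous: bool = True) -> InteractionGraph:
    """Clean interaction records into a single-component simple graph.

    Removal order (each step counted in the provenance log): ambiguous
    complex-expansion records (when ``drop_ambiguous``), self loops,
    duplicate/reciprocal pairs, then every connected component except the
    largest (ties broken by the lexicographically smallest member).
    """
    if not records:
        raise ValueError("no interaction records supplied")
    counts = {
        "parsed": len(records),
        "removed_ambiguous": 0,
        "removed_self_loop": 0,
        "removed_duplicate": 0,
        "removed_off_component": 0,
        "kept": 0,
    }
    seen: set[tuple[str, str]] = set()
    edges: list[tuple[str, str]] = []
    for rec in records:
        if drop_ambiguous and rec.ambiguous_complex_expansion:
            counts["removed_ambiguous"] += 1
            continue
        if rec.id_a == rec.id_b:
            counts["removed_self_loop"] += 1
            continue
        key = (rec.id_a, rec.id_b) if rec.id_a <= rec.id_b else (rec.id_b, rec.id_a)
        if key in seen:
            counts["removed_duplicate"] += 1
            continue
        seen.add(key)
        edges.append(key)
    if not edges:
        raise ValueError("empty graph: no edges survive cleaning")

    names = sorted({x for e in edges for x in e})
    idx = {name: i for i, name in enumerate(names)}
    g = ig.Graph(n=len(names), edges=[(idx[a], idx[b]) for a, b in edges])
    comps = g.connected_components()
    sizes = [len(c) for c in comps]
    # keep the largest component; ties go to the component holding the
    # lexicographically smallest identifier, for determinism
    max_size = max(sizes)
    tied = [c for c in range(len(comps)) if sizes[c] == max_size]
    best = min(tied, key=lambda c: min(names[v] for v in comps[c]))

    keep_nodes = set(comps[best])
    kept_edges = [(a, b) for a, b in edges if idx[a] in keep_nodes]
    counts["removed_off_component"] = len(edges) - len(kept_edges)
    counts["kept"] = len(kept_edges)
    counts["removed_isolated_nodes"] = len(names) - len(keep_nodes)

    out = InteractionGraph.from_edges(kept_edges)
    out.provenance = {
        "records": counts,
        "n_nodes": out.n,
        "n_edges": out.m,
        "drop_ambiguous": drop_ambiguous,
    }
    logger.info(
        "build_graph: %d nodes, %d edges kept (%s)", out.n, out.m,
        ", ".join(f"{k}={v}" for k, v in counts.items()),
    )
    return out


def write_graph(g: InteractionGraph, edge_path, provenance_path=None) -> None:
    """Write the cleaned edge list as TSV plus an optional JSON provenance log."""
    with open(edge_path, "w") as fh:
        for a, b in sorted(g.edge_set()):
            fh.write(f"{a}\t{b}\n")
    if provenance_path is not None:
        with open(provenance_path, "w") as fh:
            json.dump(g.provenance, fh, indent=2, sort_keys=True)
            fh.write("\n")
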