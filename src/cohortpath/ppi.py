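"""Thresholded protein-protein interaction graphs and ECC module detection.

Interactions arrive as a 3-column table (protein1, protein2,
combined_score); edges below the confidence threshold (default 0.700, the
conventional high-confidence cut) are dropped. Modules are found by an
agglomerative scheme driven by the edge clustering coefficient

    ECC(u, v) = (z(u, v) + 1) / min(deg(u) - 1, deg(v) - 1)

where ``z`` counts the triangles through the edge; edges interior to dense
neighborhoods score high, bridges score low. Edges are processed in
descending ECC order and endpoints merged (union-find) while ECC stays at or
above a threshold — the agglomerative edge-clustering-coefficient module
detection of the FAG-EC family. A pendant edge (an endpoint of degree 1)
has an undefined ratio and is assigned ECC = 0 by convention.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from cohortpath.errors import FormatError

logger = logging.getLogger(__name__)

DEFAULT_SCORE_THRESHOLD = 0.700


def read_ppi_table(path, threshold: float = DEFAULT_SCORE_THRESHOLD) -> nx.Graph:
    """Read and threshold a scored interaction table into a simple graph.

    Scores may be 0-1 floats or the 1-1000 integer dialect (auto-detected by
    the maximum and rescaled). Edges are kept iff ``score >= threshold``;
    duplicate pairs collapse to their maximum score; self-interactions are
    ignored. A header row is tolerated.
    """
    rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            try:
                score = float(fields[2])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise FormatError(
                    f"{path}:{lineno}: unparseable score {fields[2]!r}"
                ) from None
            rows.append((fields[0], fields[1], score))

    if rows:
        mx = max(r[2] for r in rows)
        if mx > 1.0:  # 1-1000 integer dialect
            rows = [(u, v, s / 1000.0) for u, v, s in rows]
        bad = [(i, s) for i, (_, _, s) in enumerate(rows) if not (0 <= s <= 1)]
        if bad:
            raise FormatError(f"{path}: scores outside [0, 1] after rescaling: {bad[:3]}")

    g = nx.Graph()
    for u, v, score in rows:
        if u == v:
            continue
        if g.has_edge(u, v):
            g[u][v]["combined_score"] = max(g[u][v]["combined_score"], score)
        else:
            g.add_edge(u, v, combined_score=score)
    drop = [(u, v) for u, v, d in g.edges(data=True) if d["combined_score"] < threshold]
    g.remove_edges_from(drop)
    g.remove_nodes_from(list(nx.isolates(g)))
    return g


def write_ppi_table(graph: nx.Graph, path) -> None:
    """Write a graph back to the 3-column scored table dialect."""
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\t{graph[u][v]['combined_score']:.3f}\n")


def annotate_membership(
    graph: nx.Graph,
    signaling_set: list[str],
    metabolism_set: list[str],
    seed_proteins: list[str] = (),
) -> nx.Graph:
    """Label each node by pathway membership.

    Labels: ``seed`` (takes precedence), ``both``, ``signaling_only``,
    ``metabolism_only``, or ``unannotated`` (logged). Mutates and returns
    the graph.
    """
    sig, met, seeds = set(signaling_set), set(metabolism_set), set(seed_proteins)
    n_unannotated = 0
    for n in graph.nodes:
        if n in seeds:
            label = "seed"
        elif n in sig and n in met:
            label = "both"
        elif n in sig:
            label = "signaling_only"
        elif n in met:
            label = "metabolism_only"
        else:
            label = "unannotated"
            n_unannotated += 1
        graph.nodes[n]["membership"] = label
    if n_unannotated:
        logger.info("annotate_membership: %d nodes in neither pathway", n_unannotated)
    return graph


def edge_clustering_coefficient(graph: nx.Graph, u: str, v: str) -> float:
    """ECC of one edge: (triangles + 1) / min(deg(u)-1, deg(v)-1); 0 for pendants."""
    if not graph.has_edge(u, v):
        raise KeyError(f"edge ({u!r}, {v!r}) not in graph")
    denom = min(graph.degree(u), graph.degree(v)) - 1
    if denom <= 0:
        return 0.0
    z = len(set(graph.neighbors(u)) & set(graph.neighbors(v)))
    return (z + 1) / denom


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller root label wins
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def fag_ec_modules(
    graph: nx.Graph,
    ecc_threshold: float = 1.0,
    min_module_size: int = 3,
) -> tuple[dict[int, set[str]], set[str]]:
    """Agglomerative ECC module detection.

    Edges are sorted by descending ECC (ties: higher combined_score, then
    lexicographic endpoints) and endpoints merged while ``ECC >=
    ecc_threshold``. Components smaller than ``min_module_size`` end up
    unassigned. Returns ``(modules, unassigned)`` with module ids numbered
    by each module's lexicographically smallest member; the partition is
    independent of input edge order because the tie-breaking is total.
    """
    uf = _UnionFind(graph.nodes)
    scored = []
    for u, v, data in graph.edges(data=True):
        a, b = sorted((u, v))
        ecc = edge_clustering_coefficient(graph, a, b)
        scored.append((-ecc, -data.get("combined_score", 0.0), a, b, ecc))
    scored.sort()
    for _, _, a, b, ecc in scored:
        if ecc >= ecc_threshold:
            uf.union(a, b)
    groups: dict[str, set[str]] = {}
    for n in graph.nodes:
        groups.setdefault(uf.find(n), set()).add(n)
    modules: dict[int, set[str]] = {}
    unassigned: set[str] = set()
    for _, members in sorted(groups.items(), key=lambda kv: min(kv[1])):
        if len(members) >= min_module_size:
            modules[len(modules)] = members
        else:
            unassigned |= members
    return modules, unassigned


def write_annotated_graphml(graph: nx.Graph, path) -> None:
    """GraphML export preserving membership labels and edge scores."""
    nx.write_graphml(graph, path)
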