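"""Graph and filter data types, file I/O and synthetic-data generators.

A vertex-filtered graph is a pair ``(G, f)`` of a finite simple undirected
graph and a real-valued *filter function* on its vertices.  This module holds
the plain containers used throughout the package, readers/writers for the
edge-list + vertex-values text format and the TU plain-text dataset format,
and the generators that produce the fixtures every other module is tested on:

* :func:`theorem2_fixture` -- a pair of vertex-filtered graphs whose ordinary
  persistence diagrams (for both ``f`` and ``-f``) coincide while their
  extended diagrams differ, witnessing that extended persistence is strictly
  more informative than ordinary persistence;
* :func:`random_graph` -- uniform simple graphs with i.i.d. uniform filter
  values, optionally re-jittered to injectivity, used as oracle-test drivers;
* :func:`loop_count_task` -- a balanced graph-classification dataset whose
  label is the first Betti number (0, 1 or 2), the synthetic task on which a
  topology-aware layer is separable while pure message passing is not.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "VertexFunctionGraph",
    "NodeFeatures",
    "LabeledGraphDataset",
    "read_graph",
    "write_graph",
    "theorem2_fixture",
    "random_graph",
    "loop_count_task",
    "read_tu_dataset",
    "betti_numbers",
]


@dataclass(frozen=True)
class VertexFunctionGraph:
    """A simple undirected graph with an optional real filter on vertices.

    Edges are stored 0-based with ``u < v`` canonical orientation and no
    duplicates or self-loops.  ``values`` is ``None`` for graphs whose filter
    is computed downstream (e.g. by a learned filtration module).
    """

    n_vertices: int
    edges: tuple[tuple[int, int], ...]
    values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_vertices < 0:
            raise ValueError("n_vertices must be non-negative")
        canon = []
        for (u, v) in self.edges:
            if u == v:
                raise ValueError(f"self-loop at vertex {u}")
            if not (0 <= u < self.n_vertices and 0 <= v < self.n_vertices):
                raise ValueError(f"edge ({u},{v}) has endpoint outside [0,{self.n_vertices})")
            canon.append((min(u, v), max(u, v)))
        if len(set(canon)) != len(canon):
            dupes = {e for e in canon if canon.count(e) > 1}
            raise ValueError(f"duplicate edges: {sorted(dupes)}")
        object.__setattr__(self, "edges", tuple(canon))
        if self.values is not None:
            vals = tuple(float(x) for x in self.values)
            if len(vals) != self.n_vertices:
                raise ValueError(
                    f"expected {self.n_vertices} vertex values, got {len(vals)}"
                )
            if not all(np.isfinite(vals)):
                raise ValueError("filter values must be finite")
            object.__setattr__(self, "values", vals)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def with_values(self, values) -> "VertexFunctionGraph":
        return VertexFunctionGraph(self.n_vertices, self.edges, tuple(values))

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_vertices, dtype=np.int64)
        for (u, v) in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def components(self) -> list[list[int]]:
        """Connected components as sorted vertex lists (union-find)."""
        parent = list(range(self.n_vertices))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for (u, v) in self.edges:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
        comps: dict[int, list[int]] = {}
        for v in range(self.n_vertices):
            comps.setdefault(find(v), []).append(v)
        return [sorted(c) for c in comps.values()]

    def disjoint_union(self, other: "VertexFunctionGraph") -> "VertexFunctionGraph":
        off = self.n_vertices
        edges = self.edges + tuple((u + off, v + off) for (u, v) in other.edges)
        values = None
        if self.values is not None and other.values is not None:
            values = self.values + other.values
        return VertexFunctionGraph(off + other.n_vertices, edges, values)


@dataclass(frozen=True)
class NodeFeatures:
    """An ``n_vertices x d`` real feature matrix attached to a graph."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[1] < 1:
            raise ValueError("feature matrix must be 2-D with at least one column")
        object.__setattr__(self, "matrix", m)

    @property
    def n_vertices(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


@dataclass
class LabeledGraphDataset:
    """Graphs with per-graph class labels for graph classification."""

    graphs: list[VertexFunctionGraph]
    features: list[NodeFeatures]
    labels: list[int]
    n_classes: int
    #: "dense" features are used as-is; "degree_index" features hold integer
    #: degree buckets meant for a learnable embedding lookup.
    feature_kind: str = "dense"

    def __post_init__(self) -> None:
        if not (len(self.graphs) == len(self.features) == len(self.labels)):
            raise ValueError("graphs, features and labels must align")
        for g, x in zip(self.graphs, self.features):
            if x.n_vertices != g.n_vertices:
                raise ValueError("feature row count must equal n_vertices")
        for y in self.labels:
            if not (0 <= y < self.n_classes):
                raise ValueError(f"label {y} outside [0,{self.n_classes})")

    def __len__(self) -> int:
        return len(self.graphs)


# ---------------------------------------------------------------------------
# Edge-list + values text I/O
# ---------------------------------------------------------------------------

def read_graph(edge_list_path, values_path=None, n_vertices: int | None = None
               ) -> VertexFunctionGraph:
    """Read a graph from an edge-list file and an optional vertex-values file.

    The edge list holds one ``u v`` pair per line (whitespace separated,
    0-based); blank lines and ``#`` comments are ignored.  The values file
    holds one ``vertex value`` pair per line and must cover every vertex.
    Unless ``n_vertices`` is given, the vertex count is ``1 + max index``
    over both files.
    """
    edges: list[tuple[int, int]] = []
    max_idx = -1
    for lineno, line in enumerate(Path(edge_list_path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{edge_list_path}:{lineno}: expected 'u v', got {line!r}")
        try:
            u, v = int(parts[0]), int(parts[1])
        except ValueError:
            raise ValueError(f"{edge_list_path}:{lineno}: non-integer vertex index") from None
        if u == v:
            raise ValueError(f"{edge_list_path}:{lineno}: self-loop at vertex {u}")
        e = (min(u, v), max(u, v))
        if e in edges:
            raise ValueError(f"{edge_list_path}:{lineno}: duplicate edge {e}")
        edges.append(e)
        max_idx = max(max_idx, u, v)

    values = None
    if values_path is not None:
        vals: dict[int, float] = {}
        for lineno, line in enumerate(Path(values_path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{values_path}:{lineno}: expected 'vertex value'")
            try:
                v = int(parts[0])
            except ValueError:
                raise ValueError(f"{values_path}:{lineno}: non-integer vertex index") from None
            try:
                x = float(parts[1])
            except ValueError:
                raise ValueError(f"{values_path}:{lineno}: non-numeric value {parts[1]!r}") from None
            if not np.isfinite(x):
                raise ValueError(f"{values_path}:{lineno}: non-finite value")
            if v in vals:
                raise ValueError(f"{values_path}:{lineno}: duplicate value for vertex {v}")
            vals[v] = x
            max_idx = max(max_idx, v)
        n = n_vertices if n_vertices is not None else max_idx + 1
        missing = [v for v in range(n) if v not in vals]
        if missing:
            raise ValueError(f"{values_path}: missing value for vertices {missing}")
        values = tuple(vals[v] for v in range(n))
    n = n_vertices if n_vertices is not None else max_idx + 1
    return VertexFunctionGraph(max(n, 0), tuple(edges), values)


def write_graph(g: VertexFunctionGraph, edge_list_path, values_path=None) -> None:
    """Write a graph in the format :func:`read_graph` accepts (round-trips)."""
    Path(edge_list_path).write_text(
        "".join(f"{u} {v}\n" for (u, v) in g.edges))
    if values_path is not None:
        if g.values is None:
            raise ValueError("graph has no filter values to write")
        Path(values_path).write_text(
            "".join(f"{i} {x!r}\n" for i, x in enumerate(g.values)))


# ---------------------------------------------------------------------------
# Fixtures and synthetic data
# ---------------------------------------------------------------------------

def _triangle(values) -> VertexFunctionGraph:
    return VertexFunctionGraph(3, ((0, 1), (1, 2), (0, 2)), tuple(values))


def theorem2_fixture() -> tuple[VertexFunctionGraph, VertexFunctionGraph]:
    """The pair of vertex-filtered graphs separating extended from ordinary PH.

    ``g1`` is the disjoint union of a triangle with vertex values (1,3,5) and
    one with (2,3,4); ``g2`` unions triangles (1,3,4) and (2,3,5).  Both have
    component minima {1,2} and maxima {4,5}, so ordinary persistence of ``f``
    and of ``-f`` cannot tell them apart, but extended persistence matches the
    global maximum 5 with minimum 1 in ``g1`` and with minimum 2 in ``g2``.
    """
    g1 = _triangle((1, 3, 5)).disjoint_union(_triangle((2, 3, 4)))
    g2 = _triangle((1, 3, 4)).disjoint_union(_triangle((2, 3, 5)))
    return g1, g2


def random_graph(n: int, m: int, seed: int, injective: bool = True
                 ) -> VertexFunctionGraph:
    """Uniform simple graph on ``n`` vertices with ``m`` edges.

    Filter values are i.i.d. uniform(0,1); with ``injective`` they are
    re-drawn until pairwise distinct (almost surely immediate).  Reproducible
    from ``seed``.
    """
    max_m = n * (n - 1) // 2
    if not (0 <= m <= max_m):
        raise ValueError(f"m={m} infeasible for n={n} (max {max_m})")
    rng = np.random.default_rng(seed)
    all_edges = list(itertools.combinations(range(n), 2))
    idx = rng.choice(len(all_edges), size=m, replace=False) if m else []
    edges = tuple(all_edges[i] for i in sorted(idx))
    values = rng.uniform(0.0, 1.0, size=n)
    if injective:
        while len(set(values.tolist())) < n:  # pragma: no cover - p ~ 0
            values = rng.uniform(0.0, 1.0, size=n)
    return VertexFunctionGraph(n, edges, tuple(values))


def betti_numbers(g: VertexFunctionGraph) -> tuple[int, int]:
    """(β0, β1): connected components and independent cycles, via union-find."""
    b0 = len(g.components())
    b1 = g.n_edges - g.n_vertices + b0
    return b0, b1


def _random_connected(n: int, extra_edges: int, rng: np.random.Generator
                      ) -> VertexFunctionGraph:
    """Random labelled tree on ``n`` vertices plus ``extra_edges`` chords."""
    t = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
    edges = {(min(u, v), max(u, v)) for (u, v) in t.edges()}
    non_edges = [e for e in itertools.combinations(range(n), 2) if e not in edges]
    picks = rng.choice(len(non_edges), size=extra_edges, replace=False) if extra_edges else []
    for i in picks:
        edges.add(non_edges[i])
    perm = rng.permutation(n)  # relabel so structure is not index-aligned
    relabeled = {(min(perm[u], perm[v]), max(perm[u], perm[v])) for (u, v) in edges}
    return VertexFunctionGraph(n, tuple(sorted(relabeled)))


def loop_count_task(n_graphs: int, seed: int, n_vertices: int = 8
                    ) -> LabeledGraphDataset:
    """Balanced dataset labelled by the first Betti number β1 ∈ {0, 1, 2}.

    Connected graphs of matched size: random trees (label 0), unicyclic
    (label 1) and bicyclic (label 2) graphs.  Node features are uninformative
    all-ones so only structure can drive classification.
    """
    if n_graphs < 6:
        raise ValueError("need at least 2 graphs per class")
    rng = np.random.default_rng(seed)
    per_class = n_graphs // 3
    counts = [per_class + (1 if c < n_graphs % 3 else 0) for c in range(3)]
    graphs, feats, labels = [], [], []
    for label, cnt in enumerate(counts):
        for _ in range(cnt):
            g = _random_connected(n_vertices, extra_edges=label, rng=rng)
            assert betti_numbers(g) == (1, label)
            graphs.append(g)
            feats.append(NodeFeatures(np.ones((n_vertices, 1))))
            labels.append(label)
    order = rng.permutation(len(graphs))
    return LabeledGraphDataset(
        [graphs[i] for i in order], [feats[i] for i in order],
        [labels[i] for i in order], n_classes=3)


# ---------------------------------------------------------------------------
# TU plain-text dataset format
# ---------------------------------------------------------------------------

_UNINFORMATIVE = {"REDDIT-BINARY"}


def read_tu_dataset(root, name: str) -> LabeledGraphDataset:
    """Load a TU-format graph-classification dataset from ``root/name``.

    Expects the plain-text files ``DS_A.txt`` (adjacency as ``u, v`` pairs,
    1-based global vertex ids), ``DS_graph_indicator.txt`` (graph id per
    vertex) and ``DS_graph_labels.txt``.  Node features follow the TDA-style
    protocol: integer degree-bucket indices for a learnable embedding, except
    for REDDIT-BINARY whose features are uninformative all-ones.
    """
    d = Path(root) / name
    adj = d / f"{name}_A.txt"
    indicator = d / f"{name}_graph_indicator.txt"
    glabels = d / f"{name}_graph_labels.txt"
    for p in (adj, indicator, glabels):
        if not p.exists():
            raise FileNotFoundError(f"missing TU file: {p}")

    graph_of = [int(x) for x in indicator.read_text().split()]
    n_total = len(graph_of)
    n_graphs = max(graph_of)
    # contiguous local indexing per graph
    local, counts = [], [0] * (n_graphs + 1)
    for gid in graph_of:
        if gid < 1 or gid > n_graphs:
            raise ValueError(f"inconsistent graph indicator id {gid}")
        local.append(counts[gid])
        counts[gid] += 1

    edge_sets: list[set[tuple[int, int]]] = [set() for _ in range(n_graphs)]
    for lineno, line in enumerate(adj.read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        try:
            u, v = (int(t) for t in line.replace(",", " ").split())
        except ValueError:
            raise ValueError(f"{adj}:{lineno}: malformed adjacency row") from None
        if not (1 <= u <= n_total and 1 <= v <= n_total):
            raise ValueError(f"{adj}:{lineno}: vertex id outside indicator range")
        gu, gv = graph_of[u - 1], graph_of[v - 1]
        if gu != gv:
            raise ValueError(f"{adj}:{lineno}: edge crosses graphs {gu} and {gv}")
        if u == v:
            continue  # TU files occasionally carry self-loops; simple graphs only
        a, b = local[u - 1], local[v - 1]
        edge_sets[gu - 1].add((min(a, b), max(a, b)))

    raw_labels = [int(x) for x in glabels.read_text().split()]
    if len(raw_labels) != n_graphs:
        raise ValueError("graph label count does not match indicator")
    classes = sorted(set(raw_labels))
    remap = {c: i for i, c in enumerate(classes)}

    graphs, feats = [], []
    uninformative = name in _UNINFORMATIVE
    for gid in range(1, n_graphs + 1):
        g = VertexFunctionGraph(counts[gid], tuple(sorted(edge_sets[gid - 1])))
        graphs.append(g)
        if uninformative:
            feats.append(NodeFeatures(np.ones((g.n_vertices, 1))))
        else:
            feats.append(NodeFeatures(g.degrees().astype(np.float64)[:, None]))
    return LabeledGraphDataset(
        graphs, feats, [remap[c] for c in raw_labels], len(classes),
        feature_kind="dense" if uninformative else "degree_index")
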