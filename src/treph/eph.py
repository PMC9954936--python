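"""Exact extended persistent homology for vertex-filtered graphs.

Extended persistence scans a graph ``(G, f)`` twice: bottom-up along the
sublevel filtration ``{f <= a}`` and then top-down along the superlevel
filtration ``{f >= a}``.  Every vertex and edge therefore appears twice, once
per pass; these *algebraic simplices* (``V, E`` ascending and ``V̄, Ē``
descending) are the basis of a Z2 boundary matrix whose left-to-right
reduction pairs **all** of them.  The pairs fall into four classes:

========  =============  ==========================================
class     pair shape     feature
========  =============  ==========================================
Ord0      (v, e)         finite 0-dim feature of the ascending pass
Ext0      (v, v̄)        a connected component: its min matched to its max
Ext1      (e, ē)         an independent loop: its max matched to its min
Rel1      (v̄, ē)        0-dim feature of ``-f`` (descending pass)
========  =============  ==========================================

Each pair contributes the point ``(f(birth), f(death))`` to its class's
persistence diagram; coordinates are raw filter values (the reversed order
on the descending axis is a plotting convention, not a sign change).  Unlike
ordinary persistence there are no points at infinity, which is what lets a
downstream layer vectorize and aggregate every feature uniformly.

The module also provides ordinary persistence (union-find, for ablations and
cross-checks), the projection of extended diagrams onto ordinary ones, and an
independent oracle that recomputes Ord0/Rel1/Ext0 and the Ext1 coordinate
multisets without any matrix reduction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .graph import VertexFunctionGraph

__all__ = [
    "Simplex",
    "FiltrationOrder",
    "ExtendedPairing",
    "ExtendedDiagrams",
    "OrdinaryDiagrams",
    "sublevel_subgraph",
    "build_filtration_order",
    "build_extended_boundary_matrix",
    "reduce_and_pair",
    "extract_diagrams",
    "build_locating_map",
    "extended_persistence",
    "eph",
    "ph",
    "ph_from_eph",
    "oracle_diagrams",
    "diagrams_to_json",
    "diagrams_to_csv",
]

CLASSES = ("ord0", "ext0", "ext1", "rel1")

SCHEMA_VERSION = 1


class Simplex(NamedTuple):
    """An algebraic simplex: a vertex or edge in one of the two passes."""

    ascending: bool
    is_edge: bool
    index: int  # vertex index, or position into g.edges

    def __repr__(self) -> str:  # compact: v3, e1, v̄3, ē1
        tag = ("e" if self.is_edge else "v") + ("" if self.ascending else "~")
        return f"{tag}{self.index}"


@dataclass(frozen=True)
class FiltrationOrder:
    """Total entrance order of all ``2(|V|+|E|)`` algebraic simplices.

    The ascending block (all of ``V ∪ E``) comes first, sorted by
    ``(entry value, vertex-before-edge, index)``; the descending block is
    sorted by ``(-entry value, vertex-before-edge, index)``.  Entry values:
    a vertex enters at ``f(v)`` in both passes; an ascending edge at the max
    of its endpoint values, a descending edge at the min.  The tie rules make
    the order (hence all downstream output) deterministic for non-injective
    filters.
    """

    graph: VertexFunctionGraph
    sequence: tuple[Simplex, ...]
    position: dict[Simplex, int]
    entry_value: dict[Simplex, float]

    def __len__(self) -> int:
        return len(self.sequence)


def sublevel_subgraph(g: VertexFunctionGraph, a: float) -> VertexFunctionGraph:
    """The subgraph induced on ``{v : f(v) <= a}`` (vertices re-indexed)."""
    if g.values is None:
        raise ValueError("graph has no filter values")
    keep = [v for v in range(g.n_vertices) if g.values[v] <= a]
    remap = {v: i for i, v in enumerate(keep)}
    edges = tuple((remap[u], remap[v]) for (u, v) in g.edges
                  if u in remap and v in remap)
    return VertexFunctionGraph(len(keep), edges, tuple(g.values[v] for v in keep))


def build_filtration_order(g: VertexFunctionGraph,
                           values=None) -> FiltrationOrder:
    """Order all algebraic simplices of ``(G, f)`` by time of entrance."""
    f = g.values if values is None else tuple(float(x) for x in values)
    if f is None:
        raise ValueError("graph has no filter values")
    if len(f) != g.n_vertices or not all(math.isfinite(x) for x in f):
        raise ValueError("need one finite filter value per vertex")
    g = VertexFunctionGraph(g.n_vertices, g.edges, f)

    asc: list[tuple[tuple, Simplex, float]] = []
    desc: list[tuple[tuple, Simplex, float]] = []
    for v in range(g.n_vertices):
        asc.append(((f[v], 0, v), Simplex(True, False, v), f[v]))
        desc.append(((-f[v], 0, v), Simplex(False, False, v), f[v]))
    for i, (u, v) in enumerate(g.edges):
        hi, lo = max(f[u], f[v]), min(f[u], f[v])
        asc.append(((hi, 1, i), Simplex(True, True, i), hi))
        desc.append(((-lo, 1, i), Simplex(False, True, i), lo))
    asc.sort(key=lambda t: t[0])
    desc.sort(key=lambda t: t[0])

    sequence = tuple(s for (_, s, _) in asc) + tuple(s for (_, s, _) in desc)
    position = {s: i for i, s in enumerate(sequence)}
    entry = {s: val for (_, s, val) in asc + desc}
    return FiltrationOrder(g, sequence, position, entry)


def build_extended_boundary_matrix(order: FiltrationOrder) -> list[set[int]]:
    """Z2 boundary matrix of the cone construction, as sparse column sets.

    One column per simplex, indexed by filtration position.  An ascending
    vertex bounds nothing; an ascending edge bounds its ascending endpoints;
    a descending vertex ``v̄`` bounds (the cone over) its ascending copy; a
    descending edge ``ē`` bounds the ascending edge and both descending
    endpoints.  Every row index is strictly below its column index.
    """
    g = order.graph
    pos = order.position
    cols: list[set[int]] = []
    for j, s in enumerate(order.sequence):
        if s.ascending:
            if not s.is_edge:
                col: set[int] = set()
            else:
                u, v = g.edges[s.index]
                col = {pos[Simplex(True, False, u)], pos[Simplex(True, False, v)]}
        else:
            if not s.is_edge:
                col = {pos[Simplex(True, False, s.index)]}
            else:
                u, v = g.edges[s.index]
                col = {pos[Simplex(True, True, s.index)],
                       pos[Simplex(False, False, u)],
                       pos[Simplex(False, False, v)]}
        if any(r >= j for r in col):
            raise RuntimeError(f"ordering violation in column of {s}")
        cols.append(col)
    return cols


@dataclass(frozen=True)
class ExtendedPairing:
    """The full pairing of algebraic simplices, classified into four classes.

    ``pairs`` lists ``(birth, death)`` with the birth the earlier simplex in
    the filtration order; ``classes`` gives the corresponding class name.
    """

    order: FiltrationOrder
    pairs: tuple[tuple[Simplex, Simplex], ...]
    classes: tuple[str, ...]

    def by_class(self, cls: str) -> list[tuple[Simplex, Simplex]]:
        return [p for p, c in zip(self.pairs, self.classes) if c == cls]

    def counts(self) -> dict[str, int]:
        return {c: self.classes.count(c) for c in CLASSES}


def _classify(birth: Simplex, death: Simplex) -> str:
    shape = (birth.ascending, birth.is_edge, death.ascending, death.is_edge)
    table = {
        (True, False, True, True): "ord0",   # (v, e)
        (True, False, False, False): "ext0",  # (v, v̄)
        (True, True, False, True): "ext1",   # (e, ē)
        (False, False, False, True): "rel1",  # (v̄, ē)
    }
    if shape not in table:
        raise RuntimeError(f"impossible pair shape ({birth}, {death})")
    return table[shape]


def reduce_and_pair(matrix: list[set[int]],
                    order: FiltrationOrder) -> ExtendedPairing:
    """Standard left-to-right column reduction over Z2; pair lowest ones.

    A column is repeatedly reduced by adding the earlier column sharing its
    lowest nonzero row until it is zero or its lowest row is unclaimed; the
    row/column of each surviving lowest one form a (birth, death) pair.  For
    graphs every algebraic simplex ends up in exactly one pair.
    """
    cols = [set(c) for c in matrix]
    low_inv: dict[int, int] = {}
    pairs, classes = [], []
    for j, col in enumerate(cols):
        while col:
            low = max(col)
            k = low_inv.get(low)
            if k is None:
                low_inv[low] = j
                birth, death = order.sequence[low], order.sequence[j]
                pairs.append((birth, death))
                classes.append(_classify(birth, death))
                break
            col ^= cols[k]
    paired = {s for p in pairs for s in p}
    if len(paired) != len(order.sequence):
        missing = [s for s in order.sequence if s not in paired]
        raise RuntimeError(f"extended persistence left simplices unpaired: {missing}")
    return ExtendedPairing(order, tuple(pairs), tuple(classes))


@dataclass(frozen=True)
class ExtendedDiagrams:
    """Four multisets of planar points, one per extended-persistence class.

    Birth/death coordinates are raw filter values; the per-class inequality
    (``birth <= death`` for Ord0/Ext0, ``birth >= death`` for Ext1/Rel1)
    encodes the reversed descending axis.
    """

    ord0: tuple[tuple[float, float], ...]
    ext0: tuple[tuple[float, float], ...]
    ext1: tuple[tuple[float, float], ...]
    rel1: tuple[tuple[float, float], ...]

    def __getitem__(self, cls: str) -> tuple[tuple[float, float], ...]:
        return getattr(self, cls)

    def total_points(self) -> int:
        return sum(len(self[c]) for c in CLASSES)


def extract_diagrams(pairing: ExtendedPairing) -> ExtendedDiagrams:
    """Read the four diagrams off a pairing: point = (entry(birth), entry(death))."""
    ev = pairing.order.entry_value
    pts: dict[str, list[tuple[float, float]]] = {c: [] for c in CLASSES}
    for (b, d), c in zip(pairing.pairs, pairing.classes):
        pts[c].append((ev[b], ev[d]))
    return ExtendedDiagrams(**{c: tuple(sorted(pts[c])) for c in CLASSES})


def build_locating_map(order: FiltrationOrder) -> dict[Simplex, int]:
    """Map each algebraic simplex to the vertex marking its entrance.

    Vertex simplices locate at themselves.  An edge locates at whichever of
    its endpoints enters *later in the same pass* — the vertex whose arrival
    brings the edge into the filtration (argmax f ascending / argmin f
    descending, under injectivity).
    """
    g = order.graph
    pos = order.position
    locate: dict[Simplex, int] = {}
    for s in order.sequence:
        if not s.is_edge:
            locate[s] = s.index
        else:
            u, v = g.edges[s.index]
            pu = pos[Simplex(s.ascending, False, u)]
            pv = pos[Simplex(s.ascending, False, v)]
            locate[s] = u if pu > pv else v
    return locate


def extended_persistence(g: VertexFunctionGraph, values=None
                         ) -> tuple[ExtendedDiagrams, ExtendedPairing, dict[Simplex, int]]:
    """Full extended persistence of ``(G, f)``: diagrams, pairing, locating map."""
    order = build_filtration_order(g, values)
    pairing = reduce_and_pair(build_extended_boundary_matrix(order), order)
    return extract_diagrams(pairing), pairing, build_locating_map(order)


def eph(g: VertexFunctionGraph, filters: np.ndarray
        ) -> list[tuple[ExtendedDiagrams, ExtendedPairing, dict[Simplex, int]]]:
    """Extended persistence for each column of an ``n_vertices x df`` filter matrix."""
    filters = np.asarray(filters, dtype=np.float64)
    if filters.ndim == 1:
        filters = filters[:, None]
    if filters.shape[0] != g.n_vertices or filters.shape[1] < 1:
        raise ValueError("filters must be n_vertices x df with df >= 1")
    if not np.all(np.isfinite(filters)):
        raise ValueError("filter values must be finite")
    return [extended_persistence(g, filters[:, k]) for k in range(filters.shape[1])]


# ---------------------------------------------------------------------------
# Ordinary persistence (union-find) and the projection from EPH
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrdinaryDiagrams:
    """Ordinary sublevel persistence: dim-0 and dim-1 multisets.

    Essential features carry ``math.inf`` as their death coordinate.
    """

    dim0: tuple[tuple[float, float], ...]
    dim1: tuple[tuple[float, float], ...]


class _ElderUnionFind:
    """Union-find whose merges follow the elder rule of 0-dim persistence."""

    def __init__(self) -> None:
        self.parent: dict[int, int] = {}
        self.birth: dict[int, tuple[float, int]] = {}  # (value, entrance position)

    def add(self, v: int, birth: tuple[float, int]) -> None:
        self.parent[v] = v
        self.birth[v] = birth

    def find(self, v: int) -> int:
        while self.parent[v] != v:
            self.parent[v] = self.parent[self.parent[v]]
            v = self.parent[v]
        return v

    def union(self, u: int, v: int) -> tuple[float, int] | None:
        """Merge; return the younger component's birth, or None if already joined."""
        ru, rv = self.find(u), self.find(v)
        if ru == rv:
            return None
        if self.birth[ru] > self.birth[rv]:
            ru, rv = rv, ru
        self.parent[rv] = ru  # elder ru survives
        return self.birth[rv]


def _zero_dim_pairs(g: VertexFunctionGraph, f, sign: float
                    ) -> tuple[list[tuple[float, float]], list[float], list[float]]:
    """Elder-rule sweep of ``sign*f``; returns (finite pairs, essential births,
    cycle-edge entry values), all reported in the original ``f`` scale."""
    n = g.n_vertices
    verts = sorted(range(n), key=lambda v: (sign * f[v], v))
    vpos = {v: i for i, v in enumerate(verts)}
    edges = sorted(range(g.n_edges),
                   key=lambda i: (max(sign * f[u] for u in g.edges[i]), i))
    uf = _ElderUnionFind()
    finite: list[tuple[float, float]] = []
    cycles: list[float] = []
    vi = 0
    for ei in edges:
        u, v = g.edges[ei]
        t = max(sign * f[u], sign * f[v])
        while vi < n and sign * f[verts[vi]] <= t:
            uf.add(verts[vi], (sign * f[verts[vi]], vpos[verts[vi]]))
            vi += 1
        died = uf.union(u, v)
        if died is None:
            cycles.append(sign * t)
        else:
            finite.append((sign * died[0], sign * t))
    while vi < n:
        uf.add(verts[vi], (sign * f[verts[vi]], vpos[verts[vi]]))
        vi += 1
    roots = {uf.find(v) for v in range(n)}
    essential = [sign * uf.birth[r][0] for r in roots]
    return finite, essential, cycles


def ph(g: VertexFunctionGraph, values=None) -> OrdinaryDiagrams:
    """Ordinary sublevel persistence of ``(G, f)`` by union-find.

    dim-0: a finite (birth, death) per merger plus one essential
    ``(component min, inf)`` per component; dim-1: ``(entry value, inf)`` per
    cycle-creating edge.
    """
    f = g.values if values is None else tuple(float(x) for x in values)
    if f is None:
        raise ValueError("graph has no filter values")
    finite, essential, cycles = _zero_dim_pairs(g, f, sign=1.0)
    dim0 = sorted(finite + [(b, math.inf) for b in essential])
    dim1 = sorted((c, math.inf) for c in cycles)
    return OrdinaryDiagrams(tuple(dim0), tuple(dim1))


def ph_from_eph(d: ExtendedDiagrams) -> OrdinaryDiagrams:
    """Project extended diagrams onto ordinary persistence.

    dim-0 is Ord0 plus ``(birth, inf)`` per Ext0 point; dim-1 is
    ``(birth, inf)`` per Ext1 point.  Pairing information (which max goes
    with which min) is discarded — exactly what ordinary persistence loses.
    """
    dim0 = sorted(list(d.ord0) + [(a, math.inf) for (a, _) in d.ext0])
    dim1 = sorted((c, math.inf) for (c, _) in d.ext1)
    return OrdinaryDiagrams(tuple(dim0), tuple(dim1))


def oracle_diagrams(g: VertexFunctionGraph, values=None) -> dict[str, object]:
    """Reduction-free cross-check of the extended diagrams.

    * Ord0 by the elder-rule union-find sweep of ``f``;
    * Rel1 as the 0-dim features of ``-f``, negated back (the symmetry of
      extended persistence);
    * Ext0 as ``(min f, max f)`` per connected component;
    * Ext1 only as the birth multiset (ascending cycle-edge entries) and the
      death multiset (descending cycle-edge entries) — which birth pairs with
      which death is exactly what this oracle cannot see.

    Returns dict with keys ord0, rel1, ext0 (sorted point tuples) and
    ext1_births / ext1_deaths (sorted value tuples).
    """
    f = g.values if values is None else tuple(float(x) for x in values)
    if f is None:
        raise ValueError("graph has no filter values")
    asc_finite, _, asc_cycles = _zero_dim_pairs(g, f, sign=1.0)
    desc_finite, _, desc_cycles = _zero_dim_pairs(g, f, sign=-1.0)
    ext0 = [(min(f[v] for v in comp), max(f[v] for v in comp))
            for comp in g.components()]
    # a 0-dim pair (b, d) of -f is a Rel1 pair persisting (in f-scale) d -> b
    rel1 = [(b, d) for (b, d) in desc_finite]
    return {
        "ord0": tuple(sorted(asc_finite)),
        "rel1": tuple(sorted(rel1)),
        "ext0": tuple(sorted(ext0)),
        "ext1_births": tuple(sorted(asc_cycles)),
        "ext1_deaths": tuple(sorted(desc_cycles)),
    }


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def diagrams_to_json(d: ExtendedDiagrams) -> str:
    payload = {"schema_version": SCHEMA_VERSION}
    payload.update({c: [list(p) for p in d[c]] for c in CLASSES})
    return json.dumps(payload, indent=2)


def diagrams_to_csv(results) -> str:
    """CSV rows (filter_index, class, birth, death, birth_vertex, death_vertex)
    for the output of :func:`eph` (or a single :func:`extended_persistence`
    triple wrapped in a list)."""
    lines = ["filter_index,class,birth,death,birth_vertex,death_vertex"]
    for k, (_, pairing, locate) in enumerate(results):
        ev = pairing.order.entry_value
        for (b, d), c in zip(pairing.pairs, pairing.classes):
            lines.append(f"{k},{c},{ev[b]!r},{ev[d]!r},{locate[b]},{locate[d]}")
    return "\n".join(lines) + "\n"
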