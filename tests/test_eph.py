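"""Extended-persistence engine: ordering, reduction, diagrams, oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from treph import (
    Simplex,
    VertexFunctionGraph,
    betti_numbers,
    build_extended_boundary_matrix,
    build_filtration_order,
    build_locating_map,
    diagrams_to_csv,
    diagrams_to_json,
    eph,
    extended_persistence,
    extract_diagrams,
    oracle_diagrams,
    ph,
    ph_from_eph,
    random_graph,
    reduce_and_pair,
    sublevel_subgraph,
    theorem2_fixture,
)
from treph.eph import CLASSES


def V(i):
    return Simplex(True, False, i)


def E(i):
    return Simplex(True, True, i)


def Vd(i):
    return Simplex(False, False, i)


def Ed(i):
    return Simplex(False, True, i)


class TestSublevelSubgraph:
    @pytest.mark.parametrize("a,n,m", [(2, 1, 0), (3, 2, 1), (5, 3, 3), (0.5, 0, 0)])
    def test_triangle_thresholds(self, t135, a, n, m):
        sub = sublevel_subgraph(t135, a)
        assert (sub.n_vertices, sub.n_edges) == (n, m)


class TestFiltrationOrder:
    def test_triangle_order_by_hand(self, t135):
        order = build_filtration_order(t135)
        assert order.sequence == (
            V(0), V(1), E(0), V(2), E(1), E(2),
            Vd(2), Vd(1), Ed(1), Vd(0), Ed(0), Ed(2))

    def test_single_vertex(self):
        g = VertexFunctionGraph(1, (), (0.5,))
        assert build_filtration_order(g).sequence == (V(0), Vd(0))

    def test_equal_values_tie_broken_by_index_in_both_passes(self):
        g = VertexFunctionGraph(2, (), (1.0, 1.0))
        seq = build_filtration_order(g).sequence
        assert seq == (V(0), V(1), Vd(0), Vd(1))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_order_invariants_on_random_graphs(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 12))
        m = int(r.integers(0, n * (n - 1) // 2 + 1))
        g = random_graph(n, m, seed=seed)
        order = build_filtration_order(g)
        assert len(order) == 2 * (n + m)
        pos = order.position
        # ascending block strictly precedes descending block
        assert all(pos[s] < 2 * (n + m) for s in order.sequence)
        asc = order.sequence[: n + m]
        assert all(s.ascending for s in asc)
        # edges after both endpoints, in each pass
        for i, (u, v) in enumerate(g.edges):
            assert pos[E(i)] > max(pos[V(u)], pos[V(v)])
            assert pos[Ed(i)] > max(pos[Vd(u)], pos[Vd(v)])
        # monotone entry values within each block
        av = [order.entry_value[s] for s in asc]
        dv = [order.entry_value[s] for s in order.sequence[n + m:]]
        assert av == sorted(av) and dv == sorted(dv, reverse=True)


class TestBoundaryMatrix:
    def test_k2_descending_edge_column(self, k2):
        order = build_filtration_order(k2)
        cols = build_extended_boundary_matrix(order)
        assert len(cols) == 6
        pos = order.position
        assert cols[pos[Ed(0)]] == {pos[E(0)], pos[Vd(0)], pos[Vd(1)]}

    def test_single_vertex_cone_column(self):
        g = VertexFunctionGraph(1, (), (0.0,))
        order = build_filtration_order(g)
        cols = build_extended_boundary_matrix(order)
        assert cols == [set(), {0}]

    def test_triangle_has_three_empty_columns(self, t135):
        cols = build_extended_boundary_matrix(build_filtration_order(t135))
        assert len(cols) == 12
        assert sum(1 for c in cols if not c) == 3

    def test_strictly_upper_triangular(self):
        g = random_graph(10, 20, seed=9)
        order = build_filtration_order(g)
        for j, col in enumerate(build_extended_boundary_matrix(order)):
            assert all(r < j for r in col)


class TestReduceAndPair:
    def test_k2_pairing_by_hand(self, k2):
        _, pairing, _ = extended_persistence(k2)
        got = {(p, c) for p, c in zip(pairing.pairs, pairing.classes)}
        assert got == {((V(1), E(0)), "ord0"),
                       ((V(0), Vd(1)), "ext0"),
                       ((Vd(0), Ed(0)), "rel1")}

    def test_triangle_pairing_by_hand(self, t135):
        _, pairing, _ = extended_persistence(t135)
        got = set(zip(pairing.pairs, pairing.classes))
        assert ((V(0), Vd(2)), "ext0") in got
        assert ((E(2), Ed(2)), "ext1") in got
        assert {p[0] for p, c in got if c == "ord0"} == {V(1), V(2)}
        assert {p[0] for p, c in got if c == "rel1"} == {Vd(0), Vd(1)}

    def test_isolated_vertex_single_ext0_pair(self):
        g = VertexFunctionGraph(1, (), (0.3,))
        _, pairing, _ = extended_persistence(g)
        assert pairing.pairs == ((V(0), Vd(0)),)
        assert pairing.classes == ("ext0",)


class TestDiagrams:
    def test_triangle_diagrams_by_hand(self, t135):
        d, _, _ = extended_persistence(t135)
        assert d.ord0 == ((3, 3), (5, 5))
        assert d.ext0 == ((1, 5),)
        assert d.ext1 == ((5, 1),)
        assert d.rel1 == ((1, 1), (3, 3))

    def test_theorem2_extended_matchings(self, thm2_pair):
        g1, g2 = thm2_pair
        d1 = extended_persistence(g1)[0]
        d2 = extended_persistence(g2)[0]
        assert d1.ext0 == ((1, 5), (2, 4))
        assert d2.ext0 == ((1, 4), (2, 5))
        assert d1.ext1 != d2.ext1

    def test_per_class_birth_death_inequalities(self):
        for seed in range(10):
            g = random_graph(12, 18, seed=seed)
            d = extended_persistence(g)[0]
            assert all(b <= dd for b, dd in d.ord0 + d.ext0)
            assert all(b >= dd for b, dd in d.ext1 + d.rel1)


class TestLocatingMap:
    def test_triangle_edge_locations(self, t135):
        locate = build_locating_map(build_filtration_order(t135))
        assert locate[E(2)] == 2   # ascending (0,2): value-5 endpoint enters later
        assert locate[Ed(2)] == 0  # descending: value-1 endpoint enters later
        for v in range(3):
            assert locate[V(v)] == v and locate[Vd(v)] == v

    def test_edge_locates_at_extremal_endpoint_under_injectivity(self):
        g = random_graph(10, 25, seed=2)
        locate = build_locating_map(build_filtration_order(g))
        for i, (u, v) in enumerate(g.edges):
            assert locate[E(i)] == max((u, v), key=lambda w: g.values[w])
            assert locate[Ed(i)] == min((u, v), key=lambda w: g.values[w])


class TestMultiFilter:
    def test_matches_single_filter(self, t135):
        res = eph(t135, np.array(t135.values, dtype=float))
        assert len(res) == 1
        assert res[0][0] == extended_persistence(t135)[0]

    def test_identical_columns_identical_results(self, t135):
        f = np.array(t135.values, dtype=float)
        res = eph(t135, np.stack([f, f], axis=1))
        assert res[0][0] == res[1][0]

    def test_df8_gives_32_diagrams(self):
        g = random_graph(6, 8, seed=1)
        res = eph(g, np.random.default_rng(0).uniform(size=(6, 8)))
        assert sum(len(d[0][c]) >= 0 for d in res for c in CLASSES) == 32

    def test_nonfinite_filters_rejected(self, t135):
        with pytest.raises(ValueError):
            eph(t135, np.array([1.0, np.nan, 2.0]))


class TestOrdinaryPersistence:
    def test_triangle_by_hand(self, t135):
        d = ph(t135)
        assert d.dim0 == ((1, math.inf), (3, 3), (5, 5))
        assert d.dim1 == ((5, math.inf),)

    def test_tree_has_empty_dim1(self):
        g = VertexFunctionGraph(5, ((0, 1), (1, 2), (1, 3), (3, 4)),
                                (0.1, 0.5, 0.2, 0.9, 0.4))
        assert ph(g).dim1 == ()

    def test_theorem2_pair_indistinguishable(self, thm2_pair):
        g1, g2 = thm2_pair
        assert ph(g1) == ph(g2)
        neg = lambda g: [-x for x in g.values]
        assert ph(g1, neg(g1)) == ph(g2, neg(g2))

    def test_projection_from_extended(self, t135, thm2_pair):
        assert ph_from_eph(extended_persistence(t135)[0]) == ph(t135)
        g1, _ = thm2_pair
        d = ph_from_eph(extended_persistence(g1)[0])
        assert [p for p in d.dim0 if math.isinf(p[1])] == [(1, math.inf), (2, math.inf)]


class TestOracle:
    def test_triangle(self, t135):
        o = oracle_diagrams(t135)
        assert o["ext0"] == ((1, 5),)
        assert o["ext1_births"] == (5.0,) and o["ext1_deaths"] == (1.0,)

    def test_forest_has_no_cycles(self):
        g = VertexFunctionGraph(4, ((0, 1), (2, 3)), (1, 2, 3, 4))
        o = oracle_diagrams(g)
        assert o["ext1_births"] == () and o["ext1_deaths"] == ()

    def test_single_cycle_components_fully_determined(self):
        cyc = lambda vals: VertexFunctionGraph(
            len(vals), tuple((i, (i + 1) % len(vals)) for i in range(len(vals))), vals)
        g = cyc((1, 5, 2)).disjoint_union(cyc((0, 4, 3, 6)))
        d = extended_persistence(g)[0]
        assert set(d.ext1) == {(5, 1), (6, 0)}


class TestGlobalProperties:
    """Invariants checked across a population of random graphs."""

    def _random(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 16))
        m = int(r.integers(0, n * (n - 1) // 2 + 1))
        return random_graph(n, m, seed=seed)

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence(self, seed):
        g = self._random(seed)
        d, pairing, _ = extended_persistence(g)
        o = oracle_diagrams(g)
        assert d.ord0 == o["ord0"] and d.rel1 == o["rel1"] and d.ext0 == o["ext0"]
        assert tuple(sorted(b for b, _ in d.ext1)) == o["ext1_births"]
        assert tuple(sorted(x for _, x in d.ext1)) == o["ext1_deaths"]

    @pytest.mark.parametrize("seed", range(20))
    def test_pairing_count_identities_and_uniformity(self, seed):
        g = self._random(seed)
        _, pairing, _ = extended_persistence(g)
        c = pairing.counts()
        b0, b1 = betti_numbers(g)
        n, m = g.n_vertices, g.n_edges
        assert c["ext0"] == b0 and c["ext1"] == b1
        assert c["ord0"] + c["ext0"] == n == c["rel1"] + c["ext0"]
        assert c["ord0"] + c["ext1"] == m == c["rel1"] + c["ext1"]
        assert 2 * len(pairing.pairs) == 2 * (n + m)

    def test_disjoint_union_additivity(self):
        a, b = self._random(31), self._random(32)
        du = extended_persistence(a.disjoint_union(b))[0]
        da, db = extended_persistence(a)[0], extended_persistence(b)[0]
        for cls in CLASSES:
            assert sorted(du[cls]) == sorted(da[cls] + db[cls])

    @given(st.integers(0, 2**31 - 1), st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_shift_equivariance(self, seed, c):
        g = self._random(seed)
        d0 = extended_persistence(g)[0]
        d1 = extended_persistence(g, [x + c for x in g.values])[0]
        for cls in CLASSES:
            assert np.allclose(np.array(d1[cls]).reshape(-1, 2),
                               np.array(d0[cls]).reshape(-1, 2) + c)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_equivariance(self, seed):
        g = self._random(seed)
        h = lambda x: x ** 3 + 2 * x
        d0 = extended_persistence(g)[0]
        d1 = extended_persistence(g, [h(x) for x in g.values])[0]
        for cls in CLASSES:
            assert np.allclose(np.array(d1[cls]).reshape(-1, 2),
                               h(np.array(d0[cls], dtype=float).reshape(-1, 2)))

    @pytest.mark.parametrize("seed", range(10))
    def test_negation_symmetry(self, seed):
        g = self._random(seed)
        d = extended_persistence(g)[0]
        dn = extended_persistence(g, [-x for x in g.values])[0]
        # the descending pass of -f replays the ascending pass of f, so the
        # finite 0-dim classes swap roles with coordinates negated in place;
        # the essential classes are fixed up to negation-and-swap
        neg = lambda pts: tuple(sorted((-a, -b) for (a, b) in pts))
        negswap = lambda pts: tuple(sorted((-b, -a) for (a, b) in pts))
        assert dn.ord0 == neg(d.rel1)
        assert dn.rel1 == neg(d.ord0)
        assert dn.ext0 == negswap(d.ext0)
        assert dn.ext1 == negswap(d.ext1)

    @pytest.mark.parametrize("seed", range(10))
    def test_ph_recovered_from_eph(self, seed):
        g = self._random(seed)
        assert ph_from_eph(extended_persistence(g)[0]) == ph(g)


class TestExport:
    def test_json_schema(self, t135):
        import json
        d = extended_persistence(t135)[0]
        payload = json.loads(diagrams_to_json(d))
        assert payload["schema_version"] == 1
        assert payload["ext0"] == [[1.0, 5.0]]

    def test_csv_one_row_per_pair(self, t135):
        res = extended_persistence(t135)
        lines = diagrams_to_csv([res]).strip().splitlines()
        assert lines[0].startswith("filter_index,class,birth")
        assert len(lines) == 1 + 6
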