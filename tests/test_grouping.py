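"""Relational groups, correlation cliques and their combinations."""

import itertools

import numpy as np
import pytest

from featlink import (
    AnnotationEdge,
    CorrelationParams,
    combine_groupings,
    corgroups,
    correlation_matrix,
    correlation_test,
    relational_groups,
)

from conftest import make_table


def edge(a, b):
    return AnnotationEdge(a, b, "adduct_sibling", "", 1.0)


def partition(assignment):
    """Group-index map -> set of frozensets, ignoring numbering."""
    groups = {}
    for fid, idx in assignment.items():
        if idx is not None:
            groups.setdefault(idx, set()).add(fid)
    return {frozenset(v) for v in groups.values()}


def rt_table(ids, rts=None):
    rts = rts or {fid: float(i) for i, fid in enumerate(sorted(ids))}
    return make_table([(fid, 100.0 + i, rts[fid]) for i, fid in enumerate(sorted(ids))],
                      samples=("s1", "s2"))


class TestRelationalGroups:
    def test_components(self):
        t = rt_table({"a", "b", "c", "d", "e"})
        g = relational_groups([edge("a", "b"), edge("b", "c"), edge("d", "e")], t)
        assert partition(g) == {frozenset("abc"), frozenset("de")}
        assert g["a"] == 1 and g["d"] == 2  # numbered by earliest rt

    def test_no_edges_all_unassigned(self):
        t = rt_table({"a", "b"})
        assert set(relational_groups([], t).values()) == {None}

    def test_cycle_single_group(self):
        t = rt_table({"a", "b", "c"})
        g = relational_groups([edge("a", "b"), edge("b", "c"), edge("c", "a")], t)
        assert partition(g) == {frozenset("abc")}

    def test_indices_dense(self):
        t = rt_table(set("abcdefgh"))
        g = relational_groups([edge("a", "b"), edge("c", "d"), edge("e", "f")], t)
        used = sorted({v for v in g.values() if v is not None})
        assert used == [1, 2, 3]


class TestCorrelationMatrix:
    def test_proportional_profiles(self):
        t = make_table(
            [("a", 100.0, 10.0, (10.0, 100.0, 1000.0)),
             ("b", 120.0, 10.5, (20.0, 200.0, 2000.0))],
        )
        corr = correlation_matrix(t, CorrelationParams(min_pairs=3))
        assert corr[("a", "b")] == pytest.approx(1.0)

    def test_rt_window_restricts_pairs(self):
        t = make_table(
            [("a", 100.0, 10.0, (1.0, 2.0, 4.0)),
             ("b", 120.0, 100.0, (1.0, 2.0, 4.0))],
        )
        assert correlation_matrix(t, CorrelationParams(min_pairs=3)) == {}

    def test_min_pairs_rule(self):
        t = make_table(
            [("a", 100.0, 10.0, (10.0, 100.0, np.nan, np.nan)),
             ("b", 120.0, 10.5, (20.0, 200.0, 30.0, 40.0))],
            samples=("s1", "s2", "s3", "s4"),
        )
        assert correlation_matrix(t, CorrelationParams(min_pairs=4)) == {}

    def test_zeros_treated_as_missing(self):
        t = make_table(
            [("a", 100.0, 10.0, (0.0, 10.0, 100.0, 1000.0)),
             ("b", 120.0, 10.5, (5.0, 20.0, 200.0, 2000.0))],
            samples=("s1", "s2", "s3", "s4"),
        )
        corr = correlation_matrix(t, CorrelationParams(min_pairs=3))
        assert corr[("a", "b")] == pytest.approx(1.0)  # zero sample dropped pairwise

    def test_constant_vector_undefined(self):
        t = make_table(
            [("a", 100.0, 10.0, (5.0, 5.0, 5.0)),
             ("b", 120.0, 10.5, (1.0, 2.0, 3.0))],
        )
        assert correlation_matrix(t, CorrelationParams(min_pairs=3)) == {}


class TestCorgroups:
    def params(self):
        return CorrelationParams(min_pairs=3)

    def test_complete_triangle_one_group(self):
        t = rt_table({"a", "b", "c"})
        corr = {("a", "b"): 0.9, ("b", "c"): 0.9, ("a", "c"): 0.9}
        assert partition(corgroups(t, corr, self.params())) == {frozenset("abc")}

    def test_open_triangle_never_grouped_whole(self):
        t = rt_table({"a", "b", "c"})
        corr = {("a", "b"): 0.9, ("b", "c"): 0.9, ("a", "c"): 0.5}
        result = partition(corgroups(t, corr, self.params()))
        # equal size and equal mean correlation: earliest-eluting member (a) wins
        assert result == {frozenset("ab")}

    def test_below_threshold_no_groups(self):
        t = rt_table({"a", "b", "c"})
        corr = {("a", "b"): 0.7, ("b", "c"): 0.7, ("a", "c"): 0.7}
        assert partition(corgroups(t, corr, self.params())) == set()

    def test_threshold_is_strict(self):
        t = rt_table({"a", "b"})
        assert partition(corgroups(t, {("a", "b"): 0.8}, self.params())) == set()
        assert partition(corgroups(t, {("a", "b"): 0.8000001}, self.params())) == {
            frozenset("ab")
        }

    def test_every_corgroup_is_a_clique(self):
        rng = np.random.default_rng(11)
        ids = [f"f{i}" for i in range(10)]
        t = rt_table(set(ids))
        corr = {
            (a, b): float(rng.uniform(0, 1))
            for a, b in itertools.combinations(sorted(ids), 2)
        }
        assignment = corgroups(t, corr, self.params())
        for members in partition(assignment):
            for a, b in itertools.combinations(sorted(members), 2):
                assert corr[(a, b)] > 0.8


class TestCombineGroupings:
    def test_intersect_and_union(self):
        group = {"a": 1, "b": 1, "c": 1}
        cor = {"a": 1, "b": 1, "c": None}
        inter = combine_groupings(group, cor, "intersect")
        union = combine_groupings(group, cor, "union")
        assert partition(inter) == {frozenset("ab")}
        assert partition(union) == {frozenset("abc")}

    def test_idempotent_on_identical_inputs(self):
        g = {"a": 1, "b": 1, "c": 2, "d": 2, "e": None}
        assert partition(combine_groupings(g, g, "intersect")) == partition(g)
        assert partition(combine_groupings(g, g, "union")) == partition(g)

    def test_disjoint_assignments(self):
        g1 = {"a": 1, "b": 1, "c": None, "d": None}
        g2 = {"a": None, "b": None, "c": 1, "d": 1}
        assert partition(combine_groupings(g1, g2, "intersect")) == set()
        assert partition(combine_groupings(g1, g2, "union")) == {
            frozenset("ab"), frozenset("cd")
        }

    def test_intersect_union_pair_laws(self):
        rng = np.random.default_rng(5)
        ids = [f"f{i}" for i in range(12)]
        for _ in range(20):
            g1 = {fid: int(rng.integers(0, 4)) or None for fid in ids}
            g2 = {fid: int(rng.integers(0, 4)) or None for fid in ids}
            inter = combine_groupings(g1, g2, "intersect")
            union = combine_groupings(g1, g2, "union")
            for a, b in itertools.combinations(ids, 2):
                tog1 = g1[a] is not None and g1[a] == g1[b]
                tog2 = g2[a] is not None and g2[a] == g2[b]
                tog_i = inter[a] is not None and inter[a] == inter[b]
                tog_u = union[a] is not None and union[a] == union[b]
                if tog_i:
                    # intersect never co-groups a pair both inputs separate
                    assert tog1 or tog2
                if tog1 or tog2:
                    # union never separates a pair some input co-groups
                    assert tog_u


class TestCorrelationTest:
    def test_perfect_proportionality(self):
        t = make_table(
            [("a", 100.0, 1.0, (10.0, 100.0, 1000.0, 10.0)),
             ("b", 120.0, 1.5, (20.0, 200.0, 2000.0, 20.0))],
            samples=("s1", "s2", "s3", "s4"),
        )
        coef, p, n = correlation_test(t, "a", "b")
        assert coef == pytest.approx(1.0) and n == 4 and p is not None

    def test_too_few_pairs_undefined(self):
        t = make_table(
            [("a", 100.0, 1.0, (10.0, 100.0, np.nan)),
             ("b", 120.0, 1.5, (20.0, 200.0, 30.0))],
        )
        coef, p, n = correlation_test(t, "a", "b", CorrelationParams(min_pairs=3))
        assert coef is None and p is None and n == 2

    def test_spearman_rank_reversal(self):
        t = make_table(
            [("a", 100.0, 1.0, (1.0, 2.0, 3.0, 4.0)),
             ("b", 120.0, 1.5, (40.0, 30.0, 20.0, 10.0))],
            samples=("s1", "s2", "s3", "s4"),
        )
        coef, _, _ = correlation_test(t, "a", "b", CorrelationParams(method="spearman", min_pairs=3))
        assert coef == pytest.approx(-1.0)

    def test_unknown_id_raises(self, small_table):
        with pytest.raises(KeyError):
            correlation_test(small_table, "a", "nope")


def test_row_permutation_invariance():
    """Both groupings yield identical partitions after shuffling feature rows."""
    rng = np.random.default_rng(3)
    rows = [
        (f"f{i}", float(rng.uniform(100, 500)), float(rng.uniform(10, 14)),
         tuple(rng.lognormal(3, 1, 6)))
        for i in range(12)
    ]
    samples = tuple(f"s{j}" for j in range(6))
    edges = [edge(rows[i][0], rows[j][0]) for i, j in [(0, 1), (1, 2), (4, 5), (7, 8)]]
    params = CorrelationParams(min_pairs=4, rt_window=5.0)

    t1 = make_table(rows, samples=samples)
    shuffled = rows[:]
    rng.shuffle(shuffled)
    t2 = make_table(shuffled, samples=samples)

    assert partition(relational_groups(edges, t1)) == partition(relational_groups(edges, t2))
    c1 = corgroups(t1, correlation_matrix(t1, params), params)
    c2 = corgroups(t2, correlation_matrix(t2, params), params)
    assert partition(c1) == partition(c2)
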