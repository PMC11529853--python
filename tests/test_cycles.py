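"""Cycle enumeration, canonical forms, clustering and splicing.

The brute-force oracle enumerates every alternating simple closed walk by
trying all fragment subsets, orders and orientations, checking junction
edges pairwise -- independent of the DFS implementation it validates.
"""

import itertools

import numpy as np
import pytest

from amplicycle.coverage import CoverageProfile
from amplicycle.cycles import (
    canonicalize,
    derive_cycles,
    find_simple_cycles,
    partition_cycles,
    splice,
    validate_cycle,
)
from amplicycle.fragments import Fragment
from amplicycle.graph import AmpliconGraph


# --------------------------------------------------------------- normalizer
def _norm_signature(path, juncs):
    """Canonical signature of (oriented-fragment ring, junction signatures),
    minimal over rotations and direction reversal."""
    n = len(path)
    variants = []
    for p, j in (
        (path, juncs),
        (
            tuple((path[n - 1 - k][0], "-" if path[n - 1 - k][1] == "+" else "+") for k in range(n)),
            tuple(juncs[(n - k) % n] for k in range(n)),
        ),
    ):
        for r in range(n):
            variants.append(
                tuple((p[(r + k) % n], j[(r + k) % n]) for k in range(n))
            )
    return min(variants)


def _cycle_signature(cycle):
    juncs = tuple(
        (j.kind, j.svtype or "", tuple(sorted((j.u, j.v)))) for j in cycle.junctions
    )
    return _norm_signature(cycle.path, juncs)


def brute_force_cycles(g: AmpliconGraph):
    """All alternating simple cycles, by exhaustive enumeration."""
    edge_lookup = {}
    for eid, kind, fu, su, fv, sv, w, svtype in g.junction_edges():
        key = tuple(sorted(((fu, su), (fv, sv))))
        edge_lookup.setdefault(key, []).append((kind, svtype or "", key))
    fids = sorted(g.fragments)
    found = set()
    for size in range(1, len(fids) + 1):
        for subset in itertools.combinations(fids, size):
            first, rest = subset[0], subset[1:]
            for perm in itertools.permutations(rest):
                order = (first,) + perm
                for orients in itertools.product("+-", repeat=size - 1):
                    ring = [(first, "+")] + list(zip(perm, orients))
                    slots = []
                    ok = True
                    for k in range(size):
                        pf, po = ring[k - 1]
                        nf, no = ring[k]
                        u = (pf, "h" if po == "+" else "t")
                        v = (nf, "t" if no == "+" else "h")
                        options = edge_lookup.get(tuple(sorted((u, v))))
                        if u == v or not options:
                            ok = False
                            break
                        slots.append(options)
                    if not ok:
                        continue
                    for choice in itertools.product(*slots):
                        found.add(_norm_signature(tuple(ring), tuple(choice)))
    return found


def random_graph(rng) -> AmpliconGraph:
    g = AmpliconGraph()
    n = int(rng.integers(3, 7))
    pos = 1000
    for fid in range(n):
        chrom = "chr1" if fid < n - rng.integers(0, 3) else "chr2"
        length = int(rng.integers(1000, 5000))
        g.add_fragment(Fragment(fid, chrom, pos, pos + length, 40.0))
        pos += length + int(rng.integers(0, 2000))
    eid = 0
    frags = g.sorted_fragments()
    for a, b in zip(frags, frags[1:]):
        if a.chrom == b.chrom:
            g.add_junction((a.fid, "h"), (b.fid, "t"), "spatial",
                           float(rng.integers(1, 50)), None, eid)
            eid += 1
    seen = set()
    for _ in range(int(rng.integers(2, 8))):
        u = (int(rng.integers(0, n)), "th"[rng.integers(0, 2)])
        v = (int(rng.integers(0, n)), "th"[rng.integers(0, 2)])
        svtype = ["DEL", "DUP", "INV", "BND"][rng.integers(0, 4)]
        key = (tuple(sorted((u, v))), svtype)
        if key in seen:
            continue
        seen.add(key)
        g.add_junction(u, v, "sv", float(rng.integers(1, 100)), svtype, eid)
        eid += 1
    return g


def test_smallest_circle_single_fragment_dup():
    g = AmpliconGraph()
    g.add_fragment(Fragment(0, "chr1", 1000, 51_000, 40.0))
    g.add_junction((0, "t"), (0, "h"), "sv", 40.0, "DUP", 0)
    (cycle,) = find_simple_cycles(g)
    assert cycle.path == ((0, "+"),)
    assert cycle.total_len == 50_000
    validate_cycle(g, cycle)


def test_fig1c_cycles_include_abc_and_bd(fig1c_graph):
    g, fid = fig1c_graph
    cycles = find_simple_cycles(g)
    paths = {tuple(f for f, _ in c.path) for c in cycles}
    assert (fid["A"], fid["B"], fid["C"]) in paths
    assert (fid["B"], fid["D"]) in paths
    for c in cycles:
        validate_cycle(g, c)


def test_enumeration_is_deterministic(fig1c_graph):
    g, _ = fig1c_graph
    first = [(c.path, c.canon_key) for c in find_simple_cycles(g)]
    second = [(c.path, c.canon_key) for c in find_simple_cycles(g)]
    assert first == second


def test_matches_brute_force_on_random_small_graphs():
    """Exhaustive oracle equivalence on 200 seeded instances (<= 6 frags)."""
    rng = np.random.default_rng(20240917)
    for _ in range(200):
        g = random_graph(rng)
        impl = {_cycle_signature(c) for c in find_simple_cycles(g)}
        assert impl == brute_force_cycles(g)


def test_adding_an_sv_edge_never_removes_cycles(fig1c_graph):
    g, fid = fig1c_graph
    before = {c.canon_key for c in find_simple_cycles(g)}
    g.add_junction((fid["D"], "h"), (fid["C"], "h"), "sv", 9.0, "INV", 99)
    after = {c.canon_key for c in find_simple_cycles(g)}
    assert before <= after


class TestCanonicalize:
    def test_rotation_invariance(self, fig1c_graph):
        g, _ = fig1c_graph
        (abc,) = [c for c in find_simple_cycles(g) if len(c.path) == 3]
        from amplicycle.cycles import Cycle

        n = len(abc.path)
        for r in range(1, n):
            rotated = Cycle(
                abc.path[r:] + abc.path[:r], abc.junctions[r:] + abc.junctions[:r]
            )
            assert canonicalize(rotated, g.fragments).canon_key == abc.canon_key

    def test_reflection_invariance(self, fig1c_graph):
        g, _ = fig1c_graph
        from amplicycle.cycles import Cycle, _reverse

        for c in find_simple_cycles(g):
            rp, rj = _reverse(c.path, c.junctions)
            assert canonicalize(Cycle(rp, rj), g.fragments).canon_key == c.canon_key

    def test_is_idempotent(self, fig1c_graph):
        g, _ = fig1c_graph
        for c in find_simple_cycles(g):
            assert canonicalize(c, g.fragments).canon_key == c.canon_key

    def test_distinct_rings_over_same_fragments_differ(self):
        """ABC vs ACB with different junction sets get different keys."""
        g = AmpliconGraph()
        for i in range(3):
            g.add_fragment(Fragment(i, "chr1", 1000 + i * 1000, 2000 + i * 1000, 40.0))
        # ABC ring: A->B, B->C spatial-style sv edges + C->A closure
        g.add_junction((0, "h"), (1, "t"), "sv", 1.0, "DEL", 0)
        g.add_junction((1, "h"), (2, "t"), "sv", 1.0, "DEL", 1)
        g.add_junction((2, "h"), (0, "t"), "sv", 1.0, "DUP", 2)
        # ACB ring: A->C, C->B, B->A
        g.add_junction((0, "h"), (2, "t"), "sv", 1.0, "DUP", 3)
        g.add_junction((2, "h"), (1, "t"), "sv", 1.0, "DUP", 4)
        g.add_junction((1, "h"), (0, "t"), "sv", 1.0, "DUP", 5)
        keys = {c.canon_key: c for c in find_simple_cycles(g)}
        paths = {tuple(c.path) for c in keys.values()}
        assert ((0, "+"), (1, "+"), (2, "+")) in paths
        assert ((0, "+"), (2, "+"), (1, "+")) in paths


class TestPartition:
    def test_sharing_a_fragment_joins_clusters(self, fig1c_graph):
        g, _ = fig1c_graph
        cycles = find_simple_cycles(g)
        clusters = partition_cycles(cycles, g.fragments)
        assert len(clusters) == 1  # ABC and BD share B

    def test_disjoint_cycles_split(self):
        g = AmpliconGraph()
        g.add_fragment(Fragment(0, "chr1", 1000, 2000, 40.0))
        g.add_fragment(Fragment(1, "chr2", 1000, 2000, 40.0))
        g.add_junction((0, "t"), (0, "h"), "sv", 40.0, "DUP", 0)
        g.add_junction((1, "t"), (1, "h"), "sv", 40.0, "DUP", 1)
        clusters = partition_cycles(find_simple_cycles(g), g.fragments)
        assert len(clusters) == 2
        assert clusters[0].fragment_ids.isdisjoint(clusters[1].fragment_ids)

    def test_matches_union_find_oracle_on_random_sets(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            g = random_graph(rng)
            cycles = find_simple_cycles(g)
            if not cycles:
                continue
            clusters = partition_cycles(cycles, g.fragments)
            # oracle: repeated pairwise merging until fixpoint
            groups = [set(c.fragment_ids) for c in cycles]
            changed = True
            while changed:
                changed = False
                for i in range(len(groups)):
                    for j in range(i + 1, len(groups)):
                        if groups[i] and groups[j] and groups[i] & groups[j]:
                            groups[i] |= groups[j]
                            groups[j] = set()
                            changed = True
            oracle = sorted(frozenset(s) for s in groups if s)
            assert sorted(frozenset(c.fragment_ids) for c in clusters) == oracle


class TestDerive:
    def test_fig1c_splice_yields_abdbc(self, fig1c_graph):
        g, fid = fig1c_graph
        cycles = find_simple_cycles(g)
        abc = next(c for c in cycles if len(c.path) == 3 and fid["D"] not in c.fragment_ids)
        bd = next(c for c in cycles if set(c.fragment_ids) == {fid["B"], fid["D"]})
        merged = splice(abc, bd, g.fragments)
        assert [f for f, _ in merged.path].count(fid["B"]) == 2
        assert merged.total_len == abc.total_len + bd.total_len
        assert merged.n_parents == 2
        validate_cycle(g, merged)

    def test_single_cycle_cluster_derives_nothing(self):
        g = AmpliconGraph()
        g.add_fragment(Fragment(0, "chr1", 1000, 2000, 40.0))
        g.add_junction((0, "t"), (0, "h"), "sv", 40.0, "DUP", 0)
        (cluster,) = partition_cycles(find_simple_cycles(g), g.fragments)
        assert derive_cycles(cluster, g.fragments) == []

    def test_derived_cycles_are_valid_and_dissimilarity_capped(self, fig1c_graph):
        g, _ = fig1c_graph
        clusters = partition_cycles(find_simple_cycles(g), g.fragments)
        for cluster in clusters:
            for d in derive_cycles(cluster, g.fragments, dissim_threshold=0.8):
                validate_cycle(g, d)
                assert d.is_derived
            # a threshold of 0 blocks every splice (any shared fragment
            # implies similarity > 0)
            cluster.derived_cycles = []
            assert derive_cycles(cluster, g.fragments, dissim_threshold=0.0) == []
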