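"""Simple-cycle enumeration, canonicalization, clustering and splicing.

A cycle is an alternating closed walk in the breakpoint multigraph: fragment
edge, junction (SV or spatial) edge, fragment edge, ...  Entering a fragment
at its tail exits at its head ("+" orientation) and vice versa ("-").  A
*simple* cycle visits each fragment (hence each endpoint vertex) at most
once; structures that repeat a fragment (tandem/interspersed duplications)
are represented as *derived* cycles obtained by splicing simple cycles that
share a fragment.

Enumeration is an exhaustive depth-first search rooted at each fragment in
genomic order, expanding junction edges in descending weight order, so the
output is deterministic and -- on small graphs -- provably equal to brute
force over alternating closed walks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .fragments import Fragment
from .graph import AmpliconGraph, Vertex

__all__ = [
    "JunctionRef",
    "Cycle",
    "CycleCluster",
    "find_simple_cycles",
    "canonicalize",
    "partition_cycles",
    "derive_cycles",
    "validate_cycle",
]


@dataclass(frozen=True)
class JunctionRef:
    """The sv/spatial edge entering a fragment within a cycle."""

    edge_id: int
    kind: str  # 'sv' | 'spatial'
    svtype: str | None
    u: Vertex
    v: Vertex
    weight: float

    @property
    def endpoint_key(self) -> tuple:
        a, b = sorted([self.u, self.v])
        return (self.kind, self.svtype or "", a, b)


@dataclass
class Cycle:
    """An ordered ring of oriented fragments.

    ``junctions[i]`` is the edge entering ``path[i]`` from ``path[i-1]``
    (``junctions[0]`` closes the ring from the last fragment).
    """

    path: tuple[tuple[int, str], ...]  # ((fid, '+'|'-'), ...)
    junctions: tuple[JunctionRef, ...]
    canon_key: str = ""
    total_len: int = 0
    is_derived: bool = False
    n_parents: int = 1  # simple rings spliced into this one

    @property
    def fragment_ids(self) -> set[int]:
        return {fid for fid, _ in self.path}

    def fragment_counts(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for fid, _ in self.path:
            out[fid] = out.get(fid, 0) + 1
        return out

    def min_junction_weight(self) -> float:
        return min(j.weight for j in self.junctions)


def _entry(fid: int, orient: str) -> Vertex:
    return (fid, "t" if orient == "+" else "h")


def _exit(fid: int, orient: str) -> Vertex:
    return (fid, "h" if orient == "+" else "t")


def _flip(orient: str) -> str:
    return "-" if orient == "+" else "+"


def _reverse(path, junctions):
    n = len(path)
    rpath = tuple((path[n - 1 - k][0], _flip(path[n - 1 - k][1])) for k in range(n))
    rjunc = tuple(junctions[(n - k) % n] for k in range(n))
    return rpath, rjunc


def _rotate(path, junctions, r):
    n = len(path)
    return (
        tuple(path[(r + k) % n] for k in range(n)),
        tuple(junctions[(r + k) % n] for k in range(n)),
    )


def canonicalize(cycle: Cycle, fragments: dict[int, Fragment]) -> Cycle:
    """Rotate/reflect the ring into its canonical form.

    The canonical traversal starts at the 5'-leftmost fragment (smallest
    (chrom, start)); of the two directions (and any rotations tied on that
    fragment) the lexicographically smallest oriented sequence wins.  The
    canonical key is invariant under rotation and direction reversal.
    """
    best = None
    best_pj = None
    for path, junctions in (cycle.path, cycle.junctions), _reverse(cycle.path, cycle.junctions):
        n = len(path)
        min_frag = min((fragments[fid].chrom, fragments[fid].start) for fid, _ in path)
        for r in range(n):
            fid = path[r][0]
            if (fragments[fid].chrom, fragments[fid].start) != min_frag:
                continue
            p, j = _rotate(path, junctions, r)
            key = tuple(
                (
                    fragments[p[k][0]].chrom,
                    fragments[p[k][0]].start,
                    fragments[p[k][0]].end,
                    p[k][1],
                    j[k].endpoint_key,
                )
                for k in range(n)
            )
            if best is None or key < best:
                best = key
                best_pj = (p, j)
    path, junctions = best_pj
    total = sum(fragments[fid].length for fid, _ in path)
    return replace(
        cycle,
        path=path,
        junctions=junctions,
        canon_key="|".join(repr(k) for k in best),
        total_len=total,
    )


def validate_cycle(g: AmpliconGraph, cycle: Cycle) -> None:
    """Check the cycle is a legal alternating closed walk (raises if not)."""
    n = len(cycle.path)
    if n != len(cycle.junctions):
        raise ValueError("path/junction length mismatch")
    for i in range(n):
        prev_fid, prev_o = cycle.path[i - 1]
        fid, o = cycle.path[i]
        j = cycle.junctions[i]
        expect = {_exit(prev_fid, prev_o), _entry(fid, o)}
        if {j.u, j.v} != expect:
            raise ValueError(
                f"junction {j.edge_id} does not connect "
                f"{_exit(prev_fid, prev_o)} -> {_entry(fid, o)}"
            )
        if not g.nx_graph.has_edge(j.u, j.v, key=(j.kind, j.edge_id)):
            raise ValueError(f"junction {j.edge_id} not present in graph")


def find_simple_cycles(g: AmpliconGraph, max_cycles: int = 100_000) -> list[Cycle]:
    """Enumerate all unique simple cycles of the pruned amplicon graph.

    Deterministic: fragments are rooted in genomic order and junction edges
    expanded by descending weight (ties by target locus, SV before spatial,
    then edge id); results are canonicalized, deduplicated and sorted.
    """
    frags = g.sorted_fragments()
    index = {f.fid: i for i, f in enumerate(frags)}
    found: dict[str, Cycle] = {}

    def neighbors(vertex: Vertex):
        items = [(data, data["other"]) for data in g.junctions_at(vertex)]
        # sort: weight desc, then (chrom,pos) of target, sv before spatial, id
        def sort_key(item):
            data, other = item
            f = g.fragments[other[0]]
            pos = f.start if other[1] == "t" else f.end
            return (
                -data["weight"],
                f.chrom,
                pos,
                0 if data["kind"] == "sv" else 1,
                data["edge_id"],
            )
        return sorted(items, key=sort_key)

    for s, f0 in enumerate(frags):
        start_entry = (f0.fid, "t")
        path = [(f0.fid, "+")]
        junctions: list[JunctionRef] = []
        used = {f0.fid}

        def dfs(exit_vertex: Vertex):
            if len(found) >= max_cycles:
                return
            for data, other in neighbors(exit_vertex):
                jref = JunctionRef(
                    edge_id=data["edge_id"], kind=data["kind"],
                    svtype=data["svtype"],
                    u=exit_vertex, v=other, weight=float(data["weight"]),
                )
                if other == start_entry:
                    # jref closes the ring, i.e. it enters path[0]
                    cyc = canonicalize(
                        Cycle(tuple(path), (jref, *junctions)), g.fragments
                    )
                    found.setdefault(cyc.canon_key, cyc)
                    continue
                fid2, side2 = other
                if fid2 in used or index[fid2] <= s:
                    continue
                orient = "+" if side2 == "t" else "-"
                used.add(fid2)
                path.append((fid2, orient))
                junctions.append(jref)
                dfs(_exit(fid2, orient))
                junctions.pop()
                path.pop()
                used.discard(fid2)

        dfs((f0.fid, "h"))

    return sorted(found.values(), key=lambda c: c.canon_key)


@dataclass
class CycleCluster:
    """Connected component of simple cycles under "shares >= 1 fragment"."""

    cid: int
    simple_cycles: list[Cycle]
    derived_cycles: list[Cycle] = field(default_factory=list)

    @property
    def fragment_ids(self) -> set[int]:
        out: set[int] = set()
        for c in self.simple_cycles:
            out |= c.fragment_ids
        return out

    @property
    def all_cycles(self) -> list[Cycle]:
        return list(self.simple_cycles) + list(self.derived_cycles)


def partition_cycles(
    cycles: list[Cycle], fragments: dict[int, Fragment]
) -> list[CycleCluster]:
    """Partition simple cycles into fragment-disjoint clusters (union-find)."""
    parent: dict[int, int] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for c in cycles:
        fids = sorted(c.fragment_ids)
        for fid in fids:
            parent.setdefault(fid, fid)
        for fid in fids[1:]:
            union(fids[0], fid)

    groups: dict[int, list[Cycle]] = {}
    for c in cycles:
        root = find(next(iter(c.fragment_ids)))
        groups.setdefault(root, []).append(c)

    def group_key(root):
        fid = min(groups[root], key=lambda c: c.canon_key).path[0][0]
        f = fragments[fid]
        return (f.chrom, f.start, f.fid)

    clusters = []
    for cid, root in enumerate(sorted(groups, key=group_key)):
        clusters.append(
            CycleCluster(cid, sorted(groups[root], key=lambda c: c.canon_key))
        )
    return clusters


def _multiset_jaccard(a: dict[int, int], b: dict[int, int]) -> float:
    keys = set(a) | set(b)
    inter = sum(min(a.get(k, 0), b.get(k, 0)) for k in keys)
    union = sum(max(a.get(k, 0), b.get(k, 0)) for k in keys)
    return inter / union if union else 0.0


def splice(c1: Cycle, c2: Cycle, fragments: dict[int, Fragment]) -> Cycle | None:
    """Insert ring ``c2`` into ``c1`` at their shared fragment.

    The shared fragment with smallest (chrom, start) is the splice point; if
    it appears with opposite orientations the inserted ring is
    direction-reversed so the walk stays legal.  Returns None when the rings
    share no fragment.
    """
    shared = c1.fragment_ids & c2.fragment_ids
    if not shared:
        return None
    fid = min(shared, key=lambda x: (fragments[x].chrom, fragments[x].start, x))
    i = next(k for k, (f, _) in enumerate(c1.path) if f == fid)
    o1 = c1.path[i][1]
    p2, j2 = c2.path, c2.junctions
    occurrences = [k for k, (f, o) in enumerate(p2) if f == fid and o == o1]
    if not occurrences:
        p2, j2 = _reverse(p2, j2)
        occurrences = [k for k, (f, o) in enumerate(p2) if f == fid and o == o1]
    j = occurrences[0]
    new_path = c1.path[: i + 1] + p2[j + 1 :] + p2[: j + 1] + c1.path[i + 1 :]
    new_junc = (
        c1.junctions[: i + 1]
        + j2[j + 1 :]
        + j2[: j + 1]
        + c1.junctions[i + 1 :]
    )
    return canonicalize(
        Cycle(new_path, new_junc, is_derived=True,
              n_parents=c1.n_parents + c2.n_parents),
        fragments,
    )


def derive_cycles(
    cluster: CycleCluster,
    fragments: dict[int, Fragment],
    max_simple: int = 8,
    dissim_threshold: float = 0.8,
    max_derived: int = 256,
) -> list[Cycle]:
    """Generate derived (merged) cycles for a cluster.

    The up-to-``max_simple`` best-supported simple cycles (minimum junction
    weight, descending) are spliced pairwise -- and once more with a third
    ring -- whenever they share a fragment and their fragment-multiset
    Jaccard similarity is <= ``dissim_threshold`` (near-duplicates are never
    merged).  Results are canonical, deduplicated against the simple set,
    and capped at ``max_derived`` with a warning.
    """
    simple = sorted(
        cluster.simple_cycles,
        key=lambda c: (-c.min_junction_weight(), c.canon_key),
    )
    if len(simple) > max_simple:
        warnings.warn(
            f"cluster {cluster.cid}: {len(simple)} simple cycles, "
            f"keeping the {max_simple} best supported"
        )
        simple = simple[:max_simple]
    known = {c.canon_key for c in cluster.simple_cycles}
    derived: dict[str, Cycle] = {}
    truncated = False

    def try_add(base: Cycle, other: Cycle):
        nonlocal truncated
        if not (base.fragment_ids & other.fragment_ids):
            return None
        sim = _multiset_jaccard(base.fragment_counts(), other.fragment_counts())
        if sim > dissim_threshold:
            return None
        merged = splice(base, other, fragments)
        if merged is None or merged.canon_key in known:
            return None
        if len(derived) >= max_derived:
            truncated = True
            return None
        if merged.canon_key not in derived:
            derived[merged.canon_key] = merged
        return merged

    pairs = []
    for a in range(len(simple)):
        for b in range(len(simple)):
            if a == b:
                continue
            m = try_add(simple[a], simple[b])
            if m is not None:
                pairs.append((m, {a, b}))
    for m, used_idx in pairs:
        for cidx, c in enumerate(simple):
            if cidx in used_idx:
                continue
            try_add(m, c)

    if truncated:
        warnings.warn(f"cluster {cluster.cid}: derived cycle cap reached, truncated")
    out = sorted(derived.values(), key=lambda c: c.canon_key)
    cluster.derived_cycles = out
    return out
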