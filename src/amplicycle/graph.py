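"""Breakpoint multigraph over fragment endpoints.

Every fragment contributes a "tail" vertex (its start) and a "head" vertex
(its end) joined by a *fragment edge* weighted by mean coverage.  SV edges
join fragment boundaries according to the rearrangement type, and *spatial
edges* join genomically adjacent retained fragments (head of the left one to
tail of the right one) weighted by an estimate of the junction-spanning read
count.  Traversing a fragment tail->head is "+" (reference orientation),
head->tail is "-".

SV encoding:
  * BND, DEL  -> one edge head(left) -- tail(right)
  * DUP       -> one edge tail(left) -- head(right)
  * INV, INVDUP -> two edges head--head and tail--tail
  * BND with explicit strand/bracket information -> the single edge those
    strands dictate (covers translocations and foldback junctions)
  * INS       -> ignored (does not alter segment order)

The container is a :class:`networkx.MultiGraph`; the enumeration logic that
walks it lives in :mod:`amplicycle.cycles`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx

from .coverage import CoverageProfile
from .fragments import Fragment
from .sv import SVRecord, TYPE_SIDES

__all__ = ["AmpliconGraph", "build_graph", "prune_graph", "spatial_weight"]

Vertex = tuple[int, str]  # (fid, 't'|'h')


@dataclass
class AmpliconGraph:
    """Weighted undirected multigraph over fragment endpoint vertices."""

    nx_graph: nx.MultiGraph = field(default_factory=nx.MultiGraph)
    fragments: dict[int, Fragment] = field(default_factory=dict)

    # ------------------------------------------------------------- building
    def add_fragment(self, frag: Fragment) -> None:
        self.fragments[frag.fid] = frag
        t, h = (frag.fid, "t"), (frag.fid, "h")
        self.nx_graph.add_node(t, chrom=frag.chrom, pos=frag.start)
        self.nx_graph.add_node(h, chrom=frag.chrom, pos=frag.end)
        self.nx_graph.add_edge(
            t, h, key=("fragment", frag.fid), kind="fragment", weight=frag.mean_cov,
            svtype=None, edge_id=None,
        )

    def add_junction(
        self, u: Vertex, v: Vertex, kind: str, weight: float,
        svtype: str | None, edge_id: int, sv_len: int | None = None,
    ) -> None:
        self.nx_graph.add_edge(
            u, v, key=(kind, edge_id), kind=kind, weight=weight,
            svtype=svtype, edge_id=edge_id, sv_len=sv_len,
        )

    # -------------------------------------------------------------- queries
    def sorted_fragments(self) -> list[Fragment]:
        return sorted(self.fragments.values(), key=lambda f: (f.chrom, f.start, f.fid))

    def junctions_at(self, v: Vertex) -> list[dict]:
        """Non-fragment edges incident to ``v`` (self-loops included once)."""
        out = []
        seen = set()
        for _, other, key, data in self.nx_graph.edges(v, keys=True, data=True):
            if data["kind"] == "fragment" or key in seen:
                continue
            seen.add(key)
            out.append({"other": other, **data})
        return out

    def junction_edges(self) -> list[tuple]:
        """All sv/spatial edges as sorted tuples (for tests/serialization)."""
        rows = []
        for u, v, data in self.nx_graph.edges(data=True):
            if data["kind"] == "fragment":
                continue
            a, b = sorted([u, v])
            rows.append((data["edge_id"], data["kind"], a[0], a[1], b[0], b[1],
                         round(float(data["weight"]), 6), data["svtype"]))
        return sorted(rows, key=lambda r: (r[0],))

    def n_fragments(self) -> int:
        return len(self.fragments)

    # -------------------------------------------------------- serialization
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#edge_id\tkind\tfid_u\tside_u\tfid_v\tside_v\tweight\tsvtype\tchrom\tstart\tend\n")
            for f in self.sorted_fragments():
                fh.write(
                    f".\tfragment\t{f.fid}\tt\t{f.fid}\th\t{f.mean_cov:g}\t.\t"
                    f"{f.chrom}\t{f.start}\t{f.end}\n"
                )
            for eid, kind, fu, su, fv, sv_, w, svtype in self.junction_edges():
                fh.write(f"{eid}\t{kind}\t{fu}\t{su}\t{fv}\t{sv_}\t{w:g}\t{svtype or '.'}\t.\t.\t.\n")

    @classmethod
    def from_tsv(cls, path) -> "AmpliconGraph":
        g = cls()
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                eid, kind, fu, su, fv, sv_, w, svtype, chrom, start, end = line.rstrip("\n").split("\t")
                if kind == "fragment":
                    g.add_fragment(Fragment(int(fu), chrom, int(start), int(end), float(w)))
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                eid, kind, fu, su, fv, sv_, w, svtype, chrom, start, end = line.rstrip("\n").split("\t")
                if kind != "fragment":
                    g.add_junction(
                        (int(fu), su), (int(fv), sv_), kind, float(w),
                        None if svtype == "." else svtype, int(eid),
                    )
        return g


def spatial_weight(
    left: Fragment, right: Fragment, profile: CoverageProfile, bam=None
) -> float:
    """Junction-spanning read count between genomically adjacent fragments.

    With an alignment file, reads spanning the junction are counted; without
    one the approximation min(coverage just left of the junction, coverage
    just right of it) is used.
    """
    if left.chrom != right.chrom:
        raise ValueError("spatial edges connect fragments on the same chromosome")
    if left.end > right.start:
        raise ValueError("left fragment must precede the right one")
    if bam is not None:
        import pysam

        n = 0
        with pysam.AlignmentFile(str(bam)) as af:
            for read in af.fetch(left.chrom, max(0, left.end - 1), right.start + 1):
                if read.is_unmapped or read.reference_end is None:
                    continue
                if read.reference_start < left.end and read.reference_end > right.start:
                    n += 1
        return float(n)
    return min(
        profile.value_at(left.chrom, left.end - 1),
        profile.value_at(right.chrom, right.start),
    )


def _resolve(side: str, chrom: str, boundary: int,
             head_at: dict, tail_at: dict) -> int | None:
    if side == "h":
        return head_at.get((chrom, boundary))
    return tail_at.get((chrom, boundary))


def build_graph(
    fragments: list[Fragment],
    svs: list[SVRecord],
    profile: CoverageProfile,
    bp_map: dict[tuple[str, int], int] | None = None,
    strict: bool = True,
    max_spatial_gap: int | None = None,
) -> AmpliconGraph:
    """Encode fragments and SVs as the breakpoint multigraph.

    ``bp_map`` maps raw 1-based breakend positions to clean 0-based
    boundaries (from :func:`amplicycle.fragments.merge_breakpoints`); without
    it the raw positions are used directly.  An SV breakend that does not
    land on a fragment boundary raises (strict) or skips the record.
    """
    g = AmpliconGraph()
    for f in fragments:
        g.add_fragment(f)
    head_at = {(f.chrom, f.end): f.fid for f in fragments}
    tail_at = {(f.chrom, f.start): f.fid for f in fragments}

    eid = 0
    for r in svs:
        if r.svtype == "INS":
            continue
        b1 = (bp_map or {}).get((r.chrom1, r.pos1), r.pos1)
        b2 = (bp_map or {}).get((r.chrom2, r.pos2), r.pos2)
        if r.sides is not None:
            side_pairs = [r.sides]
        elif r.svtype in ("INV", "INVDUP"):
            side_pairs = [("h", "h"), ("t", "t")]
        else:
            side_pairs = [TYPE_SIDES.get(r.svtype, ("h", "t"))]
        weight = float(r.support) if r.support is not None else max(
            profile.value_at(r.chrom1, b1), 1.0
        )
        for s1, s2 in side_pairs:
            f1 = _resolve(s1, r.chrom1, b1, head_at, tail_at)
            f2 = _resolve(s2, r.chrom2, b2, head_at, tail_at)
            if f1 is None or f2 is None:
                msg = (f"SV {r.id}: breakend not on a fragment boundary "
                       f"({r.chrom1}:{b1}/{s1} -> {r.chrom2}:{b2}/{s2})")
                if strict:
                    raise ValueError(msg)
                warnings.warn(msg)
                continue
            g.add_junction((f1, s1), (f2, s2), "sv", weight, r.svtype, eid,
                           sv_len=r.sv_len)
            eid += 1

    _add_spatial_edges(g, profile, max_spatial_gap, start_id=eid)
    return g


def _add_spatial_edges(
    g: AmpliconGraph, profile: CoverageProfile,
    max_spatial_gap: int | None, start_id: int,
) -> None:
    eid = start_id
    frags = g.sorted_fragments()
    for left, right in zip(frags, frags[1:]):
        if left.chrom != right.chrom:
            continue
        gap = right.start - left.end
        if gap < 0:
            continue
        if max_spatial_gap is not None and gap > max_spatial_gap:
            continue
        w = spatial_weight(left, right, profile)
        g.add_junction((left.fid, "h"), (right.fid, "t"), "spatial", w, None, eid)
        eid += 1


def prune_graph(
    g: AmpliconGraph,
    profile: CoverageProfile,
    min_cov: float = 5.0,
    max_spatial_gap: int | None = None,
) -> AmpliconGraph:
    """Drop fragments with mean coverage <= min_cov (strict) and standalone
    fragments (no SV edge and no spatial neighbour), iterating to fixpoint.

    Spatial adjacency is recomputed on the survivors, so fragments separated
    only by pruned fragments become neighbours.
    """
    sv_edges = [
        (data["edge_id"], u, v, data["weight"], data["svtype"], data.get("sv_len"))
        for u, v, data in g.nx_graph.edges(data=True)
        if data["kind"] == "sv"
    ]
    keep = {fid for fid, f in g.fragments.items() if f.mean_cov > min_cov}
    while True:
        live_sv_fids = set()
        for _, u, v, _, _, _ in sv_edges:
            if u[0] in keep and v[0] in keep:
                live_sv_fids.update((u[0], v[0]))
        frags = sorted(
            (g.fragments[fid] for fid in keep), key=lambda f: (f.chrom, f.start)
        )
        has_neighbor = set()
        for left, right in zip(frags, frags[1:]):
            if left.chrom != right.chrom:
                continue
            gap = right.start - left.end
            if gap < 0 or (max_spatial_gap is not None and gap > max_spatial_gap):
                continue
            has_neighbor.update((left.fid, right.fid))
        new_keep = {fid for fid in keep if fid in live_sv_fids or fid in has_neighbor}
        if new_keep == keep:
            break
        keep = new_keep

    out = AmpliconGraph()
    for f in g.sorted_fragments():
        if f.fid in keep:
            out.add_fragment(f)
    max_eid = -1
    for eid, u, v, w, svtype, sv_len in sorted(sv_edges):
        if u[0] in keep and v[0] in keep:
            out.add_junction(u, v, "sv", w, svtype, eid, sv_len=sv_len)
            max_eid = max(max_eid, eid)
    _add_spatial_edges(out, profile, max_spatial_gap, start_id=max_eid + 1)
    return out
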