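"""Seven-rank ecDNA topology classification.

Ranked by increasing structural complexity; a ring is assigned the highest
rank whose predicate holds, since complex topologies may contain any mixture
of the lower-ranked features:

  1. SimpleCircularization -- no SV on the template
  2. SimpleSVs            -- only deletions, or only inversions
  3. MixedSVs             -- both deletions and inversions
  4. Multiregion          -- >= 2 genomic blocks on one chromosome,
                             separated by at least ``region_gap``
  5. Multichromosomal     -- fragments from >= 2 chromosomes
  6. Duplications         -- a region > 50 bp covered >= 2 times by the ring
  7. Foldbacks            -- two consecutive fragments overlapping in genomic
                             space with opposite orientations

Junction typing is geometric: an orientation flip between consecutive ring
fragments is inversion-like, a forward genomic gap is deletion-like; the
single backward circularization junction every ring carries counts as
neither.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fragments import Fragment

__all__ = ["Topology", "TOPOLOGY_NAMES", "classify_topology", "classify_ring"]

TOPOLOGY_NAMES = [
    "SimpleCircularization",
    "SimpleSVs",
    "MixedSVs",
    "Multiregion",
    "Multichromosomal",
    "Duplications",
    "Foldbacks",
]


@dataclass(frozen=True)
class Topology:
    rank: int  # 1..7
    name: str

    @classmethod
    def by_name(cls, name: str) -> "Topology":
        return cls(TOPOLOGY_NAMES.index(name) + 1, name)


def _blocks(intervals: list[tuple[str, int, int]], region_gap: int) -> int:
    """Count genomic blocks after merging intervals closer than region_gap."""
    per: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        per.setdefault(chrom, []).append((s, e))
    n = 0
    for chrom, ivs in per.items():
        ivs.sort()
        cur_end = None
        for s, e in ivs:
            if cur_end is None or s - cur_end >= region_gap:
                n += 1
            cur_end = e if cur_end is None else max(cur_end, e)
    return n


def classify_ring(
    ring: list[tuple[str, int, int, str]],
    region_gap: int = 10_000,
    dup_min_len: int = 50,
) -> Topology:
    """Classify an ordered ring of oriented genomic intervals
    (chrom, start, end, '+'|'-')."""
    n = len(ring)
    if n == 0:
        raise ValueError("empty ring")

    # (vii) foldback: consecutive opposite-orientation pair overlapping
    for i in range(n):
        c1, s1, e1, o1 = ring[i - 1]
        c2, s2, e2, o2 = ring[i]
        if c1 == c2 and o1 != o2 and min(e1, e2) - max(s1, s2) > 0:
            return Topology.by_name("Foldbacks")

    # (vi) duplications: a region > dup_min_len covered >= 2x by the ring
    events: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e, _ in ring:
        events.setdefault(chrom, []).append((s, e))
    for chrom, ivs in events.items():
        pts = sorted({p for s, e in ivs for p in (s, e)})
        for a, b in zip(pts, pts[1:]):
            depth = sum(1 for s, e in ivs if s <= a and b <= e)
            if depth >= 2 and b - a > dup_min_len:
                return Topology.by_name("Duplications")

    chroms = {chrom for chrom, *_ in ring}
    if len(chroms) >= 2:
        return Topology.by_name("Multichromosomal")

    if _blocks([(c, s, e) for c, s, e, _ in ring], region_gap) >= 2:
        return Topology.by_name("Multiregion")

    # junction typing is geometric: an orientation flip between consecutive
    # fragments marks an inversion; a footprint gap shorter than region_gap
    # marks a deletion (longer gaps were already classified Multiregion).
    # The single backward circularization junction counts as neither.
    has_inv = any(ring[i - 1][3] != ring[i][3] for i in range(n))
    has_del = False
    for chrom, ivs in events.items():
        ivs = sorted(ivs)
        cur_end = ivs[0][1]
        for s, e in ivs[1:]:
            if 0 < s - cur_end < region_gap:
                has_del = True
            cur_end = max(cur_end, e)
    if has_inv and has_del:
        return Topology.by_name("MixedSVs")
    if has_inv or has_del:
        return Topology.by_name("SimpleSVs")
    return Topology.by_name("SimpleCircularization")


def classify_topology(
    cycle,
    fragments: dict[int, Fragment],
    region_gap: int = 10_000,
    dup_min_len: int = 50,
) -> Topology:
    """Classify a :class:`~amplicycle.cycles.Cycle` against the ranking."""
    ring = [
        (fragments[fid].chrom, fragments[fid].start, fragments[fid].end, orient)
        for fid, orient in cycle.path
    ]
    return classify_ring(ring, region_gap=region_gap, dup_min_len=dup_min_len)
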