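"""Genome fragmentation: breakpoint merging and segmentation.

Raw SV breakends are clustered per chromosome (single linkage, 50 bp gap by
default) into clean breakpoints; the amplified regions are then segmented at
those breakpoints into non-overlapping fragments, the atomic unit of the
reconstruction.  n clean breakpoints strictly inside a contiguous region
yield exactly n + 1 fragments.

Coordinate conventions: VCF breakends are 1-based; clean breakpoints and
fragments are 0-based half-open.  A 1-based breakend at position p maps to
the 0-based boundary p, i.e. the left fragment ends at p (exclusive) and the
right fragment starts at p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .coverage import CoverageProfile
from .sv import SVRecord

__all__ = [
    "Breakpoint",
    "Fragment",
    "merge_breakpoints",
    "fragment_genome",
    "annotate_coverage",
    "amplified_regions",
    "write_fragments_bed",
]


@dataclass(frozen=True)
class Breakpoint:
    """A clean (merged) breakpoint; ``pos`` is the 0-based boundary."""

    chrom: str
    pos: int
    n_merged: int = 1


@dataclass
class Fragment:
    """A non-overlapping genomic interval between consecutive clean
    breakpoints, 0-based half-open."""

    fid: int
    chrom: str
    start: int
    end: int
    mean_cov: float = 0.0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"fragment {self.fid}: start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_breakpoints(
    records: list[SVRecord], window: int = 50
) -> tuple[list[Breakpoint], dict[tuple[str, int], int]]:
    """Cluster all raw breakends within ``window`` bp (single linkage) into
    clean breakpoints at the cluster median (rounded down).

    Returns the clean breakpoints and a mapping raw (chrom, 1-based pos) ->
    clean 0-based boundary, used later to attach SV edges to fragment
    boundaries.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    per: dict[str, list[int]] = {}
    for r in records:
        for chrom, pos in r.breakends:
            per.setdefault(chrom, []).append(pos)
    breakpoints: list[Breakpoint] = []
    mapping: dict[tuple[str, int], int] = {}
    for chrom in sorted(per):
        positions = sorted(set(per[chrom]))
        cluster: list[int] = []
        clusters: list[list[int]] = []
        for p in positions:
            if cluster and p - cluster[-1] > window:
                clusters.append(cluster)
                cluster = []
            cluster.append(p)
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            n = len(cl)
            median = cl[(n - 1) // 2] if n % 2 else (cl[n // 2 - 1] + cl[n // 2]) // 2
            # raw pos is 1-based; the clean boundary keeps the same coordinate
            # meaning (left fragment ends here), hence no off-by-one shift.
            breakpoints.append(Breakpoint(chrom, median, n_merged=n))
            for p in cl:
                mapping[(chrom, p)] = median
    breakpoints.sort(key=lambda b: (b.chrom, b.pos))
    return breakpoints, mapping


def amplified_regions(
    profile: CoverageProfile,
    svs: list[SVRecord] | None = None,
    threshold: float = 5.0,
    pad: int = 0,
    breakend_pad: int = 1000,
) -> list[tuple[str, int, int]]:
    """Regions worth segmenting: coverage > threshold, padded and merged,
    plus an interval around every retained SV breakend.

    Genome-wide segmentation is wasteful; fragments outside these regions
    would be pruned as low-coverage anyway.
    """
    raw = [(c, max(0, s - pad), e + pad) for c, s, e in profile.regions_above(threshold)]
    for r in svs or []:
        for chrom, pos in r.breakends:
            b = pos  # 0-based boundary
            raw.append((chrom, max(0, b - breakend_pad), b + breakend_pad))
    per: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in raw:
        per.setdefault(chrom, []).append((s, e))
    merged: list[tuple[str, int, int]] = []
    for chrom in sorted(per):
        ivs = sorted(per[chrom])
        cs, ce = ivs[0]
        for s, e in ivs[1:]:
            if s <= ce:
                ce = max(ce, e)
            else:
                merged.append((chrom, cs, ce))
                cs, ce = s, e
        merged.append((chrom, cs, ce))
    return merged


def fragment_genome(
    breakpoints: list[Breakpoint],
    regions: list[tuple[str, int, int]],
) -> list[Fragment]:
    """Segment each region at the clean breakpoints strictly inside it.

    Fragments tile every region without gaps or overlap; breakpoints falling
    outside every region are dropped with a warning.
    """
    regions = sorted(regions)
    used: set[tuple[str, int]] = set()
    fragments: list[Fragment] = []
    fid = 0
    for chrom, rs, re_ in regions:
        inner = sorted(
            b.pos for b in breakpoints if b.chrom == chrom and rs < b.pos < re_
        )
        used.update((chrom, p) for p in inner)
        used.update((chrom, b.pos) for b in breakpoints if b.chrom == chrom and b.pos in (rs, re_))
        bounds = [rs] + inner + [re_]
        for i in range(len(bounds) - 1):
            fragments.append(Fragment(fid, chrom, bounds[i], bounds[i + 1]))
            fid += 1
    for b in breakpoints:
        if (b.chrom, b.pos) not in used:
            warnings.warn(f"breakpoint {b.chrom}:{b.pos} outside every region, dropped")
    return fragments


def annotate_coverage(fragments: list[Fragment], profile: CoverageProfile) -> list[Fragment]:
    """Set each fragment's mean_cov to the length-weighted profile mean."""
    for f in fragments:
        f.mean_cov = profile.mean(f.chrom, f.start, f.end)
    return fragments


def write_fragments_bed(fragments: list[Fragment], path) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\tF{f.fid}\t{f.mean_cov:.3f}\t+\n")
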