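"""Ground-truth ecDNA template simulation and idealized fixture emission.

Templates are ordered rings of oriented genomic intervals drawn on a
synthetic two-chromosome toy genome (2 x 5 Mb).  The generator models the
chromosome weights, region position and length, small-deletion ratio,
inversion ratio, tandem-duplication ratio and foldback ratio, and can
rejection-sample towards a requested topology class.

Instead of simulating reads, aligning them and calling SVs, the emitter
writes directly what those stages would yield under ideal conditions:

  * a Sniffles-style VCF with one record per ring junction (SVTYPE inferred
    from junction geometry, DV = rounded template proportion, DR = rounded
    background coverage, STRANDS for breakend-level orientation),
  * a bedGraph coverage track equal to background + sum over templates of
    proportion x multiplicity per position, with optional Gaussian bin
    noise, breakend jitter and junction false-negative dropout,
  * a truth BED ring in the same 10-column thread format the reconstructor
    writes.

Default distribution parameters (chosen once as realistic study
conditions): region length U(50-500 kb), small deletions U(0.1-5 kb),
inverted / duplicated / folded segments U(5-50 kb), per-element proportions
U(20-200) copies, background coverage 5x.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from .coverage import CoverageProfile
from .output import FragmentRecord, Reconstruction, write_bed
from .topology import TOPOLOGY_NAMES, classify_ring

__all__ = [
    "TOY_CHROM_SIZES",
    "TemplateSpec",
    "Template",
    "GroundTruth",
    "NoiseSpec",
    "Fixture",
    "simulate_template",
    "simulate_truth",
    "heterogeneity_truth",
    "emit_fixture",
    "mix_fixtures",
    "ring_junctions",
    "write_toy_genome_fasta",
    "detectable_templates",
]

TOY_CHROM_SIZES = {"chr1": 5_000_000, "chr2": 5_000_000}

Ring = list[tuple[str, int, int, str]]  # (chrom, start, end, '+'|'-')

_MARGIN = 2_000  # min distance between engineered breakpoints (>> merge window)


@dataclass
class TemplateSpec:
    """Probabilistic template model; deterministic given ``seed``."""

    chrom_weights: dict[str, float] | None = None
    n_regions: int = 1
    region_len: tuple[int, int] = (50_000, 500_000)
    del_ratio: float = 0.3
    inv_ratio: float = 0.3
    dup_ratio: float = 0.3
    foldback_ratio: float = 0.3
    del_len: tuple[int, int] = (100, 5_000)
    segment_len: tuple[int, int] = (5_000, 50_000)
    target_topology: str | None = None
    seed: int = 0
    chrom_sizes: dict[str, int] = field(default_factory=lambda: dict(TOY_CHROM_SIZES))

    def __post_init__(self):
        for r in (self.del_ratio, self.inv_ratio, self.dup_ratio, self.foldback_ratio):
            if not 0 <= r <= 1:
                raise ValueError("event ratios must be in [0, 1]")
        if self.target_topology is not None and self.target_topology not in TOPOLOGY_NAMES:
            raise ValueError(f"unknown topology {self.target_topology!r}")
        if self.chrom_weights is not None:
            total = sum(self.chrom_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("chrom_weights must sum to 1")


@dataclass
class Template:
    name: str
    ring: Ring
    proportion: float
    topology: str


@dataclass
class GroundTruth:
    templates: list[Template]
    background_cov: float = 5.0
    chrom_sizes: dict[str, int] = field(default_factory=lambda: dict(TOY_CHROM_SIZES))


@dataclass
class NoiseSpec:
    cov_sigma: float = 0.0  # Gaussian coverage noise per bin (x)
    bp_jitter: int = 0  # uniform breakend jitter (bp)
    fn_rate: float = 0.0  # junction false-negative dropout
    bin_size: int = 100


@dataclass
class Fixture:
    vcf: str
    coverage: str
    truth: str
    profile: CoverageProfile


# ---------------------------------------------------------------- templates
def _pick_interval(ring: Ring, rng, min_len: int) -> int | None:
    cands = [
        i for i, (_, s, e, o) in enumerate(ring) if o == "+" and e - s >= min_len
    ]
    if not cands:
        return None
    return int(rng.choice(cands))


def _apply_del(ring: Ring, rng, spec: TemplateSpec) -> bool:
    d = int(rng.integers(spec.del_len[0], spec.del_len[1] + 1))
    i = _pick_interval(ring, rng, d + 4 * _MARGIN)
    if i is None:
        return False
    chrom, s, e, o = ring[i]
    m = int(rng.integers(s + _MARGIN, e - _MARGIN - d))
    ring[i : i + 1] = [(chrom, s, m, "+"), (chrom, m + d, e, "+")]
    return True


def _apply_inv(ring: Ring, rng, spec: TemplateSpec) -> bool:
    seg = int(rng.integers(spec.segment_len[0], spec.segment_len[1] + 1))
    i = _pick_interval(ring, rng, seg + 4 * _MARGIN)
    if i is None:
        return False
    chrom, s, e, o = ring[i]
    m1 = int(rng.integers(s + _MARGIN, e - _MARGIN - seg))
    ring[i : i + 1] = [
        (chrom, s, m1, "+"),
        (chrom, m1, m1 + seg, "-"),
        (chrom, m1 + seg, e, "+"),
    ]
    return True


def _apply_dup(ring: Ring, rng, spec: TemplateSpec) -> bool:
    seg = int(rng.integers(spec.segment_len[0], spec.segment_len[1] + 1))
    i = _pick_interval(ring, rng, seg + 4 * _MARGIN)
    if i is None:
        return False
    chrom, s, e, o = ring[i]
    m1 = int(rng.integers(s + _MARGIN, e - _MARGIN - seg))
    m2 = m1 + seg
    ring[i : i + 1] = [
        (chrom, s, m1, "+"),
        (chrom, m1, m2, "+"),
        (chrom, m1, m2, "+"),
        (chrom, m2, e, "+"),
    ]
    return True


def _apply_foldback(ring: Ring, rng, spec: TemplateSpec) -> bool:
    """Fold-back-and-continue motif: forward to m, back over the last
    ``seg`` bases in reverse, then resume forward at m."""
    seg = int(rng.integers(spec.segment_len[0], spec.segment_len[1] + 1))
    i = _pick_interval(ring, rng, seg + 4 * _MARGIN)
    if i is None:
        return False
    chrom, s, e, o = ring[i]
    m = int(rng.integers(s + seg + _MARGIN, e - _MARGIN))
    ring[i : i + 1] = [
        (chrom, s, m, "+"),
        (chrom, m - seg, m, "-"),
        (chrom, m, e, "+"),
    ]
    return True


def _sample_regions(rng, spec: TemplateSpec, n: int, same_chrom: bool | None) -> Ring:
    chroms = sorted(spec.chrom_sizes)
    weights = (
        [spec.chrom_weights.get(c, 0.0) for c in chroms]
        if spec.chrom_weights
        else [1.0 / len(chroms)] * len(chroms)
    )
    for _ in range(200):
        if same_chrom is True:
            chosen = [chroms[rng.choice(len(chroms), p=weights)]] * n
        elif same_chrom is False:
            if len(chroms) < n:
                raise ValueError("not enough chromosomes for a multichromosomal template")
            chosen = list(rng.choice(chroms, size=n, replace=False))
        else:
            chosen = [chroms[rng.choice(len(chroms), p=weights)] for _ in range(n)]
        regions = []
        for chrom in chosen:
            length = int(rng.integers(spec.region_len[0], spec.region_len[1] + 1))
            hi = spec.chrom_sizes[chrom] - length - _MARGIN
            start = int(rng.integers(_MARGIN, hi))
            regions.append((chrom, start, start + length, "+"))
        # reject overlapping or nearly-adjacent regions (they must read as
        # separate blocks)
        ok = True
        per: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e, _ in regions:
            per.setdefault(chrom, []).append((s, e))
        for ivs in per.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 - e1 < 50_000:
                    ok = False
        if ok:
            return regions
    raise RuntimeError("could not place non-overlapping regions")


def _build_ring(rng, spec: TemplateSpec) -> Ring:
    target = spec.target_topology
    if target == "Multichromosomal":
        ring = _sample_regions(rng, spec, max(2, spec.n_regions), same_chrom=False)
    elif target == "Multiregion":
        ring = _sample_regions(rng, spec, max(2, spec.n_regions), same_chrom=True)
    elif target is None:
        ring = _sample_regions(rng, spec, spec.n_regions,
                               same_chrom=None if spec.n_regions > 1 else True)
    else:
        ring = _sample_regions(rng, spec, 1, same_chrom=True)

    if target is None:
        if rng.random() < spec.del_ratio:
            _apply_del(ring, rng, spec)
        if rng.random() < spec.inv_ratio:
            _apply_inv(ring, rng, spec)
        if rng.random() < spec.dup_ratio:
            _apply_dup(ring, rng, spec)
        if rng.random() < spec.foldback_ratio:
            _apply_foldback(ring, rng, spec)
        return ring

    if target == "SimpleCircularization":
        pass
    elif target == "SimpleSVs":
        kind = rng.choice(["DEL", "INV"])
        for _ in range(int(rng.integers(1, 4))):
            (_apply_del if kind == "DEL" else _apply_inv)(ring, rng, spec)
    elif target == "MixedSVs":
        _apply_del(ring, rng, spec)
        _apply_inv(ring, rng, spec)
    elif target in ("Multiregion", "Multichromosomal"):
        if rng.random() < spec.del_ratio:
            _apply_del(ring, rng, spec)
        if rng.random() < spec.inv_ratio:
            _apply_inv(ring, rng, spec)
    elif target == "Duplications":
        _apply_dup(ring, rng, spec)
        if rng.random() < spec.del_ratio:
            _apply_del(ring, rng, spec)
        if rng.random() < spec.inv_ratio:
            _apply_inv(ring, rng, spec)
    elif target == "Foldbacks":
        _apply_foldback(ring, rng, spec)
        if rng.random() < spec.del_ratio:
            _apply_del(ring, rng, spec)
        if rng.random() < spec.inv_ratio:
            _apply_inv(ring, rng, spec)
    return ring


def simulate_template(spec: TemplateSpec, max_retries: int = 50) -> Ring:
    """Draw one template ring; rejection-samples until its classified
    topology equals ``spec.target_topology`` (when requested)."""
    ss = np.random.SeedSequence(spec.seed)
    for child in ss.spawn(max_retries):
        rng = np.random.default_rng(child)
        try:
            ring = _build_ring(rng, spec)
        except RuntimeError:
            continue
        if spec.target_topology is None:
            return ring
        if classify_ring(ring).name == spec.target_topology:
            return ring
    raise RuntimeError(f"retry cap exceeded for spec {spec}")


def simulate_truth(
    n_templates: int = 1,
    seed: int = 0,
    target_topology: str | None = None,
    background_cov: float = 5.0,
    proportion_range: tuple[float, float] = (20.0, 200.0),
    spec: TemplateSpec | None = None,
    disjoint: bool = True,
) -> GroundTruth:
    """Simulate a sample: ``n_templates`` independent rings with proportions
    drawn from ``proportion_range`` over a common background.

    With ``disjoint`` (default) templates are re-drawn until their genomic
    footprints do not overlap, the co-occurrence scenario; overlapping
    footprints (heterogeneity) are built explicitly, e.g. by
    :func:`heterogeneity_truth`.
    """
    base = spec or TemplateSpec()
    master = np.random.default_rng(np.random.SeedSequence([seed, 911]))
    templates: list[Template] = []
    placed: list[tuple[str, int, int]] = []

    def overlaps(ring: Ring) -> bool:
        for chrom, s, e, _ in ring:
            for c2, s2, e2 in placed:
                if chrom == c2 and min(e, e2) - max(s, s2) > 0:
                    return True
        return False

    for i in range(n_templates):
        ring = None
        for attempt in range(50):
            sub = replace(
                base,
                target_topology=target_topology,
                seed=int(
                    np.random.SeedSequence([seed, i, attempt]).generate_state(1)[0]
                    % (2**31)
                ),
            )
            ring = simulate_template(sub)
            if not disjoint or not overlaps(ring):
                break
        else:
            raise RuntimeError("could not place disjoint templates")
        placed.extend((c, s, e) for c, s, e, _ in ring)
        prop = float(master.uniform(*proportion_range))
        templates.append(Template(f"T{i}", ring, prop, classify_ring(ring).name))
    return GroundTruth(templates, background_cov, dict(base.chrom_sizes))


def heterogeneity_truth(background_cov: float = 5.0) -> GroundTruth:
    """The canonical heterogeneity scenario: two circles, ABC at 30 copies
    and BD at 20, sharing fragment B (overlapping genomic footprints)."""
    a = ("chr1", 1_000_000, 1_200_000, "+")
    b = ("chr1", 1_200_000, 1_400_000, "+")
    d = ("chr1", 1_400_000, 1_550_000, "+")
    c = ("chr1", 1_550_000, 1_700_000, "+")
    return GroundTruth(
        templates=[
            Template("ABC", [a, b, c], 30.0, classify_ring([a, b, c]).name),
            Template("BD", [b, d], 20.0, classify_ring([b, d]).name),
        ],
        background_cov=background_cov,
    )


# ---------------------------------------------------------------- junctions
def _exit_breakend(iv) -> tuple[str, int, str]:
    chrom, s, e, o = iv
    return (chrom, e, "h") if o == "+" else (chrom, s, "t")


def _entry_breakend(iv) -> tuple[str, int, str]:
    chrom, s, e, o = iv
    return (chrom, s, "t") if o == "+" else (chrom, e, "h")


def ring_junctions(ring: Ring) -> list[tuple]:
    """Non-adjacency junctions of a ring as ((chrom,pos,side),(chrom,pos,side))
    breakend pairs (0-based boundaries); colinear exact adjacency yields no
    junction."""
    out = []
    n = len(ring)
    for i in range(n):
        b1 = _exit_breakend(ring[i - 1])
        b2 = _entry_breakend(ring[i])
        if b1[0] == b2[0] and b1[1] == b2[1] and {b1[2], b2[2]} == {"h", "t"}:
            continue  # reference-colinear adjacency
        out.append(tuple(sorted((b1, b2))))
    return out


def _junction_to_vcf(b1, b2) -> tuple[str, int, str, int, str, str]:
    """(chrom1, pos1, chrom2, pos2, svtype, strands) for a breakend pair."""
    (c1, p1, s1), (c2, p2, s2) = sorted((b1, b2))
    strands = ("+" if s1 == "h" else "-") + ("+" if s2 == "h" else "-")
    if c1 != c2:
        return c1, p1, c2, p2, "BND", strands
    if {s1, s2} == {"h", "t"}:
        head, tail = (p1, p2) if s1 == "h" else (p2, p1)
        if head < tail:
            return c1, head, c2, tail, "DEL", "+-"
        return c1, tail, c2, head, "DUP", "-+"
    return c1, p1, c2, p2, "BND", strands


# ----------------------------------------------------------------- emission
_VCF_INFO = """##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=CHR2,Number=1,Type=String,Description="Mate chromosome">
##INFO=<ID=END,Number=1,Type=Integer,Description="Mate position">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">
##INFO=<ID=STRANDS,Number=1,Type=String,Description="Breakend strands">
##FILTER=<ID=PASS,Description="All filters passed">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DR,Number=1,Type=Integer,Description="Reference-supporting reads">
##FORMAT=<ID=DV,Number=1,Type=Integer,Description="Variant-supporting reads">
"""


def _truth_reconstructions(truth: GroundTruth) -> list[Reconstruction]:
    from .topology import Topology

    recs = []
    for i, t in enumerate(truth.templates):
        frags = [
            FragmentRecord(chrom, s, e, j, o, truth.background_cov + t.proportion)
            for j, (chrom, s, e, o) in enumerate(t.ring)
        ]
        total = sum(e - s for _, s, e, _ in t.ring)
        recs.append(
            Reconstruction(
                i, frags, t.proportion, Topology.by_name(t.topology),
                "ecDNA" if total > 100_000 else "circular",
            )
        )
    return recs


def build_coverage(truth: GroundTruth, noise: NoiseSpec, rng=None) -> CoverageProfile:
    """Background + sum of proportion x multiplicity per position, with
    Gaussian per-bin noise restricted to amplified segments."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows = []
    for chrom, size in sorted(truth.chrom_sizes.items()):
        deltas: dict[int, float] = {0: 0.0, size: 0.0}
        for t in truth.templates:
            for c, s, e, _ in t.ring:
                if c != chrom:
                    continue
                deltas[s] = deltas.get(s, 0.0) + t.proportion
                deltas[e] = deltas.get(e, 0.0) - t.proportion
        positions = sorted(deltas)
        depth = 0.0
        for p, q in zip(positions, positions[1:]):
            depth += deltas[p]
            value = truth.background_cov + depth
            if depth > 0 and noise.cov_sigma > 0:
                for bs in range(p, q, noise.bin_size):
                    be = min(bs + noise.bin_size, q)
                    v = max(0.0, value + float(rng.normal(0.0, noise.cov_sigma)))
                    rows.append((chrom, bs, be, v))
            else:
                rows.append((chrom, p, q, value))
    return CoverageProfile.from_intervals(rows)


def emit_fixture(
    truth: GroundTruth,
    noise: NoiseSpec,
    outdir,
    rng=None,
    prefix: str = "sim",
) -> Fixture:
    """Write the idealized (VCF, bedGraph, truth BED) triplet for a truth."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    os.makedirs(outdir, exist_ok=True)
    vcf_path = os.path.join(outdir, f"{prefix}.sv.vcf")
    cov_path = os.path.join(outdir, f"{prefix}.coverage.bedgraph")
    truth_path = os.path.join(outdir, f"{prefix}.truth.bed")

    # aggregate junction support across templates before jitter
    support: dict[tuple, float] = {}
    for t in truth.templates:
        for j in ring_junctions(t.ring):
            support[j] = support.get(j, 0.0) + t.proportion

    records = []
    for (b1, b2), dv in sorted(support.items()):
        if noise.fn_rate > 0 and rng.random() < noise.fn_rate:
            continue
        c1, p1, c2, p2, svtype, strands = _junction_to_vcf(b1, b2)
        if noise.bp_jitter > 0:
            p1 = max(1, p1 + int(rng.integers(-noise.bp_jitter, noise.bp_jitter + 1)))
            p2 = max(1, p2 + int(rng.integers(-noise.bp_jitter, noise.bp_jitter + 1)))
            # jitter may invert near-coincident breakends (foldbacks); the
            # side-symmetric strand pairs can simply be reordered
            if c1 == c2 and p2 < p1 and strands in ("++", "--"):
                p1, p2 = p2, p1
        records.append((c1, p1, c2, p2, svtype, strands, int(round(dv))))

    dr = int(round(truth.background_cov))
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, size in sorted(truth.chrom_sizes.items()):
            fh.write(f"##contig=<ID={chrom},length={size}>\n")
        fh.write(_VCF_INFO)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSIM\n")
        for i, (c1, p1, c2, p2, svtype, strands, dv) in enumerate(
            sorted(records, key=lambda r: (r[0], r[1]))
        ):
            svlen = abs(p2 - p1) if c1 == c2 else 0
            info = f"SVTYPE={svtype};CHR2={c2};END={p2};SVLEN={svlen};STRANDS={strands}"
            fh.write(
                f"{c1}\t{p1}\tsv{i}\tN\t<{svtype}>\t.\tPASS\t{info}\tGT:DR:DV\t"
                f"0/1:{dr}:{dv}\n"
            )

    profile = build_coverage(truth, noise, rng)
    profile.to_bedgraph(cov_path)
    write_bed(_truth_reconstructions(truth), truth_path)
    return Fixture(vcf_path, cov_path, truth_path, profile)


def mix_fixtures(truths: list[GroundTruth], ratios: list[float]) -> GroundTruth:
    """In silico dilution: scale each truth by its ratio and merge.

    Proportions and backgrounds scale linearly, mirroring BAM downsampling
    followed by merging.
    """
    if len(truths) != len(ratios):
        raise ValueError("one ratio per truth required")
    if any(not (0 < r <= 1) for r in ratios):
        raise ValueError("ratios must be in (0, 1]")
    sizes = truths[0].chrom_sizes
    templates = []
    bg = 0.0
    for k, (truth, ratio) in enumerate(zip(truths, ratios)):
        if truth.chrom_sizes != sizes:
            raise ValueError("mixed truths must share chromosome sizes")
        bg += ratio * truth.background_cov
        for t in truth.templates:
            templates.append(
                Template(f"S{k}.{t.name}", list(t.ring), t.proportion * ratio, t.topology)
            )
    return GroundTruth(templates, bg, dict(sizes))


def detectable_templates(
    truth: GroundTruth,
    min_cov: float = 5.0,
    min_vaf: float = 0.01,
    prune_cov: float = 5.0,
    wgs_mean: float | None = None,
) -> list[bool]:
    """Which templates still pass the SV and coverage filters as emitted.

    A template survives the pipeline only if its junction support passes the
    SV filter, its fragments stay above the pruning threshold and its
    proportion exceeds the candidate filter's WGS-mean cut.
    """
    bg = truth.background_cov
    wgs = bg if wgs_mean is None else wgs_mean
    out = []
    for t in truth.templates:
        dv = round(t.proportion)
        dr = round(bg)
        vaf = dv / (dv + dr) if dv + dr > 0 else 0.0
        ok = (
            dv + dr >= min_cov
            and vaf >= min_vaf
            and t.proportion + bg > prune_cov
            and t.proportion > wgs
        )
        out.append(bool(ok))
    return out


def write_toy_genome_fasta(path, chrom_sizes=None, seed: int = 0, line_width: int = 80):
    """Random-sequence toy reference matching the simulator coordinates."""
    rng = np.random.default_rng(seed)
    chrom_sizes = chrom_sizes or TOY_CHROM_SIZES
    bases = np.array(list("ACGT"))
    with open(path, "w") as fh:
        for chrom, size in sorted(chrom_sizes.items()):
            fh.write(f">{chrom}\n")
            seq = "".join(bases[rng.integers(0, 4, size=size)])
            for i in range(0, size, line_width):
                fh.write(seq[i : i + line_width] + "\n")
    return path
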