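"""Reconstruction records and writers (BED-like threads, FASTA, summary).

The BED-like thread format has one row per fragment per reconstruction, in
ring order, with the header

  #chrom start end circ_id fragment_id strand coverage estimated_proportion topology label

and is lossless: :func:`read_bed` reconstructs identical records, which is
also how simulated ground-truth rings are exchanged with the evaluator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fragments import Fragment
from .topology import Topology, classify_ring

__all__ = [
    "FragmentRecord",
    "Reconstruction",
    "write_bed",
    "read_bed",
    "write_fasta",
    "write_summary",
]

BED_HEADER = (
    "#chrom\tstart\tend\tcirc_id\tfragment_id\tstrand\tcoverage\t"
    "estimated_proportion\ttopology\tlabel"
)

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class FragmentRecord:
    chrom: str
    start: int
    end: int
    fragment_id: int
    orient: str  # '+' | '-'
    mean_cov: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Reconstruction:
    """One circular element: ring-ordered fragment records plus annotation."""

    circ_id: int
    fragments: list[FragmentRecord]
    proportion: float
    topology: Topology
    label: str  # 'ecDNA' | 'circular'

    @property
    def total_len(self) -> int:
        return sum(f.length for f in self.fragments)

    @property
    def chromosomes(self) -> list[str]:
        return sorted({f.chrom for f in self.fragments})

    def ring(self) -> list[tuple[str, int, int, str]]:
        return [(f.chrom, f.start, f.end, f.orient) for f in self.fragments]


def write_bed(recs: list[Reconstruction], path) -> None:
    with open(path, "w") as fh:
        fh.write(BED_HEADER + "\n")
        for rec in recs:
            for fr in rec.fragments:
                fh.write(
                    f"{fr.chrom}\t{fr.start}\t{fr.end}\t{rec.circ_id}\t"
                    f"{fr.fragment_id}\t{fr.orient}\t{fr.mean_cov:.6g}\t"
                    f"{rec.proportion:.6g}\t{rec.topology.name}\t{rec.label}\n"
                )


def read_bed(path) -> list[Reconstruction]:
    rows: dict[int, list[tuple]] = {}
    order: list[int] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            c, s, e, cid, fid, strand, cov, prop, topo, label = line.rstrip("\n").split("\t")
            cid = int(cid)
            if cid not in rows:
                rows[cid] = []
                order.append(cid)
            rows[cid].append((c, int(s), int(e), int(fid), strand, float(cov), float(prop), topo, label))
    out = []
    for cid in order:
        frs = [
            FragmentRecord(c, s, e, fid, strand, cov)
            for c, s, e, fid, strand, cov, _, _, _ in rows[cid]
        ]
        _, _, _, _, _, _, prop, topo, label = rows[cid][0]
        out.append(Reconstruction(cid, frs, prop, Topology.by_name(topo), label))
    return out


def write_fasta(recs: list[Reconstruction], reference, path, line_width: int = 80) -> None:
    """Write each reconstruction's sequence (ring-order concatenation,
    reverse-complementing '-' fragments).  ``reference`` is a FASTA path or
    an open :class:`pyfaidx.Fasta`."""
    import pyfaidx

    ref = reference if isinstance(reference, pyfaidx.Fasta) else pyfaidx.Fasta(str(reference))
    with open(path, "w") as fh:
        for rec in recs:
            parts = []
            for fr in rec.fragments:
                if fr.chrom not in ref or fr.end > len(ref[fr.chrom]):
                    raise ValueError(
                        f"fragment {fr.chrom}:{fr.start}-{fr.end} outside reference"
                    )
                seq = str(ref[fr.chrom][fr.start : fr.end])
                parts.append(reverse_complement(seq) if fr.orient == "-" else seq)
            seq = "".join(parts)
            fh.write(
                f">circ_{rec.circ_id} length={len(seq)} proportion={rec.proportion:.6g} "
                f"topology={rec.topology.name} label={rec.label}\n"
            )
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def write_summary(recs: list[Reconstruction], path) -> None:
    with open(path, "w") as fh:
        fh.write("circ_id\tn_fragments\ttotal_len\tproportion\ttopology\tlabel\tchromosomes\n")
        for rec in recs:
            fh.write(
                f"{rec.circ_id}\t{len(rec.fragments)}\t{rec.total_len}\t"
                f"{rec.proportion:.6g}\t{rec.topology.name}\t{rec.label}\t"
                f"{','.join(rec.chromosomes)}\n"
            )
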