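"""Structural-variant records: VCF parsing and filtering.

Accepts Sniffles-1-style VCFs: SVTYPE in INFO, the mate coordinate either as
CHR2/END INFO fields or as a BND bracket ALT, read support as FORMAT DV (or
INFO RE/SUPPORT) and reference reads as FORMAT/INFO DR.  Reading goes through
cyvcf2; the tests cross-check the parse against pysam on the same fixture.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

SVTYPES = {"DEL", "DUP", "INV", "INVDUP", "BND", "TRA", "INS"}

#: breakend-side pair per SV type; 'h' = head (fragment ending at the
#: breakpoint), 't' = tail (fragment starting at it).  INV-like types imply
#: two edges (head-head and tail-tail) and are expanded at graph build.
TYPE_SIDES = {"DEL": ("h", "t"), "BND": ("h", "t"), "TRA": ("h", "t"), "DUP": ("t", "h")}

_BND_RE = re.compile(r"([\[\]])([^\[\]:]+):(\d+)([\[\]])")


@dataclass
class SVRecord:
    """One filtered SV junction with two breakends.

    Positions are 1-based (VCF convention).  ``support`` is the count of
    variant-supporting reads (the SV-edge weight), ``ref_cov`` the count of
    reference-supporting reads at the locus.  ``sides`` carries an explicit
    (side1, side2) connection for BND records with strand information;
    ``None`` means "use the per-type default encoding".
    """

    id: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    svtype: str
    filter: str = "PASS"
    support: int | None = None
    ref_cov: int | None = None
    vaf: float | None = None
    sides: tuple[str, str] | None = None
    sv_len: int | None = None

    def __post_init__(self):
        if self.pos1 < 1 or self.pos2 < 1:
            raise ValueError(f"SV {self.id}: positions must be >= 1")
        self.normalize()
        if self.vaf is None and self.support is not None and self.ref_cov is not None:
            tot = self.support + self.ref_cov
            self.vaf = self.support / tot if tot > 0 else None

    def normalize(self) -> None:
        """Order breakends so that intra-chromosomal records have pos1 <= pos2."""
        if (self.chrom1, self.pos1) > (self.chrom2, self.pos2):
            self.chrom1, self.chrom2 = self.chrom2, self.chrom1
            self.pos1, self.pos2 = self.pos2, self.pos1
            if self.sides is not None:
                self.sides = (self.sides[1], self.sides[0])

    @property
    def breakends(self) -> list[tuple[str, int]]:
        return [(self.chrom1, self.pos1), (self.chrom2, self.pos2)]


def _strands_to_sides(strands: str) -> tuple[str, str] | None:
    """Sniffles STRANDS notation: '+' joins the segment left of the breakend
    (head), '-' the segment right of it (tail)."""
    m = {"+": "h", "-": "t"}
    if len(strands) == 2 and strands[0] in m and strands[1] in m:
        return (m[strands[0]], m[strands[1]])
    return None


def _parse_bnd_alt(alt: str) -> tuple[str, int, tuple[str, str]] | None:
    """Decode a VCF breakend ALT into (mate_chrom, mate_pos, sides).

    ``t[p[`` head-tail, ``t]p]`` head-head, ``]p]t`` tail(mate is head)...
    following the VCF 4.2 breakend semantics.
    """
    m = _BND_RE.search(alt)
    if not m:
        return None
    b1, chrom, pos, b2 = m.groups()
    before = alt.index(m.group(0)) > 0  # base precedes the bracket
    if before and b1 == "[":
        sides = ("h", "t")
    elif before and b1 == "]":
        sides = ("h", "h")
    elif not before and b1 == "]":
        sides = ("t", "h")
    else:  # [p[t
        sides = ("t", "t")
    return chrom, int(pos), sides


def _first_int(val) -> int | None:
    if val is None:
        return None
    try:
        import numpy as np

        if isinstance(val, np.ndarray):
            val = val.flatten()[0]
    except Exception:
        pass
    if isinstance(val, (tuple, list)):
        val = val[0]
    try:
        i = int(val)
    except (TypeError, ValueError):
        return None
    return i if i >= 0 else None


def parse_sv_vcf(path) -> list[SVRecord]:
    """Parse a Sniffles-style SV VCF into :class:`SVRecord` objects.

    Breakends are normalized (intra-chromosomal pos1 <= pos2); VAF is computed
    from DV/DR-style counts when present, else taken from an AF-style field.
    Records lacking both END and CHR2 (and a parseable BND ALT) are skipped
    with a warning.
    """
    from cyvcf2 import VCF

    records: list[SVRecord] = []
    vcf = VCF(str(path))
    try:
        for var in vcf:
            svtype = var.INFO.get("SVTYPE")
            if svtype is None:
                warnings.warn(f"record {var.ID or var.POS}: no SVTYPE, skipped")
                continue
            svtype = str(svtype).upper()
            if svtype == "TRA":
                svtype = "BND"
            chrom1, pos1 = var.CHROM, var.POS
            chrom2 = var.INFO.get("CHR2")
            end = var.INFO.get("END")
            sides = None
            strands = var.INFO.get("STRANDS")
            if strands is not None:
                sides = _strands_to_sides(str(strands))
            if svtype == "BND" and (chrom2 is None or end is None) and var.ALT:
                parsed = _parse_bnd_alt(var.ALT[0])
                if parsed is not None:
                    chrom2, end, alt_sides = parsed
                    if sides is None:
                        sides = alt_sides
            if chrom2 is None and end is not None:
                chrom2 = chrom1  # intra-chromosomal with END only
            if chrom2 is None or end is None:
                warnings.warn(f"record {var.ID or var.POS}: no END/CHR2, skipped")
                continue

            support = None
            ref_cov = None
            try:
                dv = var.format("DV")
                if dv is not None:
                    support = _first_int(dv)
            except Exception:
                pass
            if support is None:
                support = _first_int(var.INFO.get("RE")) or _first_int(
                    var.INFO.get("SUPPORT")
                ) or _first_int(var.INFO.get("DV"))
            try:
                dr = var.format("DR")
                if dr is not None:
                    ref_cov = _first_int(dr)
            except Exception:
                pass
            if ref_cov is None:
                ref_cov = _first_int(var.INFO.get("DR"))

            vaf = None
            if support is None or ref_cov is None:
                af = var.INFO.get("AF")
                if af is not None:
                    try:
                        vaf = float(af[0] if isinstance(af, (tuple, list)) else af)
                    except (TypeError, ValueError):
                        vaf = None

            flt = var.FILTER if var.FILTER is not None else "PASS"
            records.append(
                SVRecord(
                    id=str(var.ID) if var.ID else f"{chrom1}_{pos1}_{svtype}",
                    chrom1=chrom1,
                    pos1=int(pos1),
                    chrom2=str(chrom2),
                    pos2=int(end),
                    svtype=svtype,
                    filter=str(flt),
                    support=support,
                    ref_cov=ref_cov,
                    vaf=vaf,
                    sides=sides,
                    sv_len=_first_int(var.INFO.get("SVLEN")),
                )
            )
    finally:
        vcf.close()
    return records


DEFAULT_FILTERS = frozenset({"PASS", "STRANDBIAS"})


def filter_svs(
    records: list[SVRecord],
    min_cov: float = 5.0,
    min_vaf: float = 0.01,
    allowed_filters: frozenset[str] | set[str] = DEFAULT_FILTERS,
    profile=None,
) -> list[SVRecord]:
    """Keep SVs flagged PASS/STRANDBIAS with on-target coverage >= min_cov
    and VAF >= min_vaf.

    On-target coverage is support + ref_cov when both counts exist, else the
    coverage-profile value at the first breakend (``profile`` optional).
    Records with no computable VAF are kept on that criterion (missing data
    is not evidence against the call).  Input order is preserved.
    """
    if min_cov < 0 or not (0 <= min_vaf <= 1):
        raise ValueError("min_cov must be >= 0 and min_vaf in [0, 1]")
    out = []
    for r in records:
        if r.filter not in allowed_filters:
            continue
        if r.support is not None and r.ref_cov is not None:
            cov = r.support + r.ref_cov
        elif profile is not None:
            cov = profile.value_at(r.chrom1, r.pos1 - 1)
        else:
            cov = r.support if r.support is not None else 0
        if cov < min_cov:
            continue
        if r.vaf is not None and r.vaf < min_vaf:
            continue
        out.append(r)
    return out
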