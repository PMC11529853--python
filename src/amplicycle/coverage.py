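"""Read-depth profiles as per-chromosome step functions.

A :class:`CoverageProfile` stores, for every chromosome, a sorted list of
half-open intervals with a constant coverage value (reads x).  Positions not
covered by any interval read as 0.  Profiles can be loaded from 4-column
bedGraph or from BigWig, and support length-weighted interval means, point
queries and thresholded region extraction -- the primitives the amplicon
reconstruction needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CoverageProfile"]


@dataclass
class CoverageProfile:
    """Per-chromosome step/interval coverage (reads x).

    ``data`` maps chromosome name to ``(starts, ends, values)`` numpy arrays
    sorted by start, with non-overlapping intervals.  Queries outside covered
    intervals return 0.
    """

    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_intervals(cls, intervals) -> "CoverageProfile":
        """Build from an iterable of (chrom, start, end, value) tuples."""
        per: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in intervals:
            if end <= start:
                continue
            per.setdefault(str(chrom), []).append((int(start), int(end), float(value)))
        data = {}
        for chrom, rows in per.items():
            rows.sort()
            s = np.array([r[0] for r in rows], dtype=np.int64)
            e = np.array([r[1] for r in rows], dtype=np.int64)
            v = np.array([r[2] for r in rows], dtype=float)
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"overlapping coverage intervals on {chrom}")
            if np.any(v < 0):
                raise ValueError(f"negative coverage value on {chrom}")
            data[chrom] = (s, e, v)
        return cls(data)

    @classmethod
    def from_bedgraph(cls, path) -> "CoverageProfile":
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{path}:{ln}: expected 4 bedGraph columns")
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
        return cls.from_intervals(rows)

    @classmethod
    def from_bigwig(cls, path) -> "CoverageProfile":
        import pyBigWig  # optional dependency

        bw = pyBigWig.open(str(path))
        rows = []
        try:
            for chrom in bw.chroms():
                ivs = bw.intervals(chrom)
                if ivs:
                    rows.extend((chrom, s, e, v) for s, e, v in ivs)
        finally:
            bw.close()
        return cls.from_intervals(rows)

    @classmethod
    def load(cls, path) -> "CoverageProfile":
        """Dispatch on file suffix (.bw/.bigwig -> BigWig, else bedGraph)."""
        p = str(path)
        if p.endswith((".bw", ".bigwig", ".bigWig")):
            return cls.from_bigwig(p)
        return cls.from_bedgraph(p)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.data):
                s, e, v = self.data[chrom]
                for i in range(len(s)):
                    fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{v[i]:g}\n")

    # -------------------------------------------------------------- queries
    def chroms(self) -> list[str]:
        return sorted(self.data)

    def value_at(self, chrom: str, pos: int) -> float:
        """Coverage at a single 0-based position (0 outside intervals)."""
        if chrom not in self.data:
            return 0.0
        s, e, v = self.data[chrom]
        i = int(np.searchsorted(s, pos, side="right")) - 1
        if i >= 0 and pos < e[i]:
            return float(v[i])
        return 0.0

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean over [start, end); uncovered bases count 0."""
        if end <= start:
            raise ValueError("zero-length interval")
        if chrom not in self.data:
            return 0.0
        s, e, v = self.data[chrom]
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        if hi <= lo:
            return 0.0
        ov = np.minimum(e[lo:hi], end) - np.maximum(s[lo:hi], start)
        ov = np.clip(ov, 0, None)
        return float(np.sum(ov * v[lo:hi]) / (end - start))

    def regions_above(self, threshold: float) -> list[tuple[str, int, int]]:
        """Merged intervals where coverage > threshold (strict)."""
        out: list[tuple[str, int, int]] = []
        for chrom in sorted(self.data):
            s, e, v = self.data[chrom]
            cur: tuple[int, int] | None = None
            for i in range(len(s)):
                if v[i] > threshold:
                    if cur is not None and s[i] <= cur[1]:
                        cur = (cur[0], max(cur[1], int(e[i])))
                    else:
                        if cur is not None:
                            out.append((chrom, cur[0], cur[1]))
                        cur = (int(s[i]), int(e[i]))
            if cur is not None:
                out.append((chrom, cur[0], cur[1]))
        return out

    def background_median(self, exclude: list[tuple[str, int, int]] | None = None) -> float:
        """Length-weighted median coverage outside ``exclude`` regions.

        Operational stand-in for the genome-wide (linear) mean coverage used
        by the candidate filter; robust to the amplified outliers.
        """
        lens: list[float] = []
        vals: list[float] = []
        excl: dict[str, list[tuple[int, int]]] = {}
        for chrom, s0, e0 in exclude or []:
            excl.setdefault(chrom, []).append((s0, e0))
        for chrom in self.data:
            s, e, v = self.data[chrom]
            regions = sorted(excl.get(chrom, []))
            for i in range(len(s)):
                length = int(e[i] - s[i])
                for rs, re_ in regions:
                    length -= max(0, min(int(e[i]), re_) - max(int(s[i]), rs))
                if length > 0:
                    lens.append(length)
                    vals.append(float(v[i]))
        if not vals:
            return 0.0
        order = np.argsort(vals)
        w = np.asarray(lens, dtype=float)[order]
        vv = np.asarray(vals, dtype=float)[order]
        cum = np.cumsum(w)
        idx = int(np.searchsorted(cum, cum[-1] / 2.0))
        return float(vv[min(idx, len(vv) - 1)])

    def total_mass(self) -> float:
        """Sum over all intervals of length x value (read-bases)."""
        return float(
            sum(np.sum((e - s) * v) for s, e, v in self.data.values())
        )
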