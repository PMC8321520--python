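"""Interval algebra on BED-style genomic regions.

Coordinates are 0-based half-open throughout (standard BED convention).
Operations: sort, merge, subtract, extend (optionally strand-aware),
complement against a genome table, and seeded random sampling.  Merge,
subtract and complement are per-base set operations and drop columns beyond
chrom/start/end; sort, sample and extend carry BED6 columns through.

Book-ended intervals (end == next start) merge by default, matching common
interval-toolkit behaviour; pass ``merge_book_ended=False`` to keep them
separate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GenomeTable",
    "read_bed",
    "write_bed",
    "read_genome_file",
    "sort_intervals",
    "merge_intervals",
    "subtract_intervals",
    "extend_intervals",
    "complement_intervals",
    "sample_intervals",
    "total_length",
]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open region, optionally with BED6 name/score/strand."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains_pos(self, pos_1based: int) -> bool:
        """Whether a 1-based coordinate (e.g. a VCF POS) falls inside."""
        return self.start < pos_1based <= self.end


class GenomeTable(dict):
    """Ordered chrom → length (bp) map, as read from a two-column genome file."""

    def __init__(self, lengths: dict[str, int] | Iterable[tuple[str, int]] = ()):
        super().__init__(lengths)
        for chrom, length in self.items():
            if length < 1:
                raise ValueError(f"chromosome {chrom!r} has length {length}")


def read_genome_file(path) -> GenomeTable:
    table = GenomeTable()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, length = line.split("\t")[:2]
            table[chrom] = int(length)
    return GenomeTable(table)


def read_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(
                GenomicInterval(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    name=f[3] if len(f) > 3 else None,
                    score=f[4] if len(f) > 4 else None,
                    strand=f[5] if len(f) > 5 else None,
                )
            )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            opt = [iv.name, iv.score, iv.strand]
            while opt and opt[-1] is None:
                opt.pop()
            fields += [x if x is not None else "." for x in opt]
            fh.write("\t".join(fields) + "\n")


def sort_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Sort by (chrom, start, end); stable for equal keys."""
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_intervals(
    intervals: Sequence[GenomicInterval], merge_book_ended: bool = True
) -> list[GenomicInterval]:
    """Union overlapping (and, by default, book-ended) intervals per chromosome."""
    out: list[GenomicInterval] = []
    cur: GenomicInterval | None = None
    for iv in sort_intervals(intervals):
        bare = GenomicInterval(iv.chrom, iv.start, iv.end)
        if cur is not None and cur.chrom == bare.chrom:
            joined = bare.start < cur.end or (merge_book_ended and bare.start == cur.end)
            if joined:
                if bare.end > cur.end:
                    cur = replace(cur, end=bare.end)
                continue
        if cur is not None:
            out.append(cur)
        cur = bare
    if cur is not None:
        out.append(cur)
    return out


def subtract_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Per-base set difference a \\ b, emitted as maximal merged intervals."""
    b_merged: dict[str, list[GenomicInterval]] = {}
    for iv in merge_intervals(b):
        b_merged.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for iv in merge_intervals(a):
        pieces = [(iv.start, iv.end)]
        for cut in b_merged.get(iv.chrom, ()):
            nxt = []
            for s, e in pieces:
                if cut.end <= s or cut.start >= e:
                    nxt.append((s, e))
                    continue
                if cut.start > s:
                    nxt.append((s, cut.start))
                if cut.end < e:
                    nxt.append((cut.end, e))
            pieces = nxt
        out.extend(GenomicInterval(iv.chrom, s, e) for s, e in pieces)
    return sort_intervals(out)


def extend_intervals(
    intervals: Sequence[GenomicInterval],
    upstream: int,
    downstream: int,
    genome: GenomeTable,
    strand_aware: bool = False,
) -> list[GenomicInterval]:
    """Grow each interval by upstream/downstream bp, clipped to [0, chrom length].

    With ``strand_aware`` the up/down amounts are swapped on the minus strand;
    by default strand is ignored (upstream extends start, downstream extends
    end).
    """
    out = []
    for iv in intervals:
        if iv.chrom not in genome:
            raise KeyError(f"chromosome {iv.chrom!r} not in genome table")
        up, down = upstream, downstream
        if strand_aware and iv.strand == "-":
            up, down = down, up
        start = max(0, iv.start - up)
        end = min(genome[iv.chrom], iv.end + down)
        out.append(replace(iv, start=start, end=end))
    return out


def complement_intervals(
    intervals: Sequence[GenomicInterval], genome: GenomeTable
) -> list[GenomicInterval]:
    """Bases of the genome not covered by ``intervals``, per chromosome."""
    merged: dict[str, list[GenomicInterval]] = {}
    for iv in merge_intervals(intervals):
        if iv.chrom not in genome:
            raise KeyError(f"chromosome {iv.chrom!r} not in genome table")
        if iv.end > genome[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome length"
            )
        merged.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom, length in genome.items():
        prev = 0
        for iv in merged.get(chrom, ()):
            if iv.start > prev:
                out.append(GenomicInterval(chrom, prev, iv.start))
            prev = iv.end
        if prev < length:
            out.append(GenomicInterval(chrom, prev, length))
    return out


def sample_intervals(
    intervals: Sequence[GenomicInterval], n: int, seed: int
) -> list[GenomicInterval]:
    """Seeded simple random subset without replacement, re-sorted."""
    if n > len(intervals):
        raise ValueError(f"cannot sample {n} of {len(intervals)} intervals")
    rng = np.random.Generator(np.random.PCG64(seed))
    idx = rng.choice(len(intervals), size=n, replace=False)
    return sort_intervals([intervals[i] for i in idx])


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in intervals)
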