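"""VCF parsing, site and locus filtering, splitting, and table utilities.

The in-memory container is :class:`VariantTable`: an ordered list of
:class:`VariantRecord` plus the sample list and the original ``##`` header
lines.  Files are read through :mod:`pysam` (plain or bgzip VCF text) and
written back as VCF v4.x text, so read → write → read is the identity on the
canonical dialect (records, samples and genotype phase flags preserved).

Conventions
-----------
* VCF POS is 1-based; BED intervals are 0-based half-open, so a record at
  POS ``p`` lies inside ``(start, end)`` iff ``start < p <= end``.
* Allele *classes* are decided from the called genotypes: a site is
  *invariant* when exactly one distinct allele is called, *biallelic* with
  two, *multiallelic* with three or more (the ALT column may list alleles
  nobody carries).
* MAF/MAC are computed over called alleles only; at a multiallelic site the
  MAF is the frequency of the least frequent called allele.
* "PASS required" is strict: the FILTER column must be exactly ``PASS``;
  a missing FILTER (``.``) fails the requirement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .bed import GenomicInterval

__all__ = [
    "Genotype",
    "VariantRecord",
    "VariantTable",
    "SiteFilterSpec",
    "LocusFilterSpec",
    "read_vcf",
    "write_vcf",
    "filter_sites",
    "filter_loci",
    "split_by_loci",
    "concat_vcfs",
    "merge_vcfs",
    "sort_vcf",
    "list_chromosomes",
    "list_samples",
    "is_cpg_site",
]

MISSING = None  # allele-index placeholder for "."


@dataclass(frozen=True)
class Genotype:
    """Per-sample call: allele indices into [REF]+ALTs (None = missing)."""

    alleles: tuple[int | None, ...]
    phased: bool = False

    @property
    def is_missing(self) -> bool:
        return any(a is None for a in self.alleles)

    @property
    def is_het(self) -> bool:
        called = [a for a in self.alleles if a is not None]
        return len(set(called)) > 1

    def __str__(self) -> str:
        sep = "|" if self.phased else "/"
        return sep.join("." if a is None else str(a) for a in self.alleles)


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...] = ()
    id: str | None = None
    qual: float | None = None
    filter: tuple[str, ...] = ()
    info: dict = field(default_factory=dict)
    genotypes: list[Genotype] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"POS must be >= 1, got {self.pos}")
        if not self.ref:
            raise ValueError("REF must be non-empty")
        n_alleles = 1 + len(self.alts)
        for gt in self.genotypes:
            for a in gt.alleles:
                if a is not None and not (0 <= a < n_alleles):
                    raise ValueError(
                        f"allele index {a} out of range at {self.chrom}:{self.pos}"
                    )

    # -- per-record summaries -------------------------------------------------

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts

    @property
    def is_indel(self) -> bool:
        return any(len(a) != 1 for a in self.alleles if a not in ("*",))

    @property
    def is_snp(self) -> bool:
        return not self.is_indel

    def called_allele_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for gt in self.genotypes:
            for a in gt.alleles:
                if a is not None:
                    counts[a] = counts.get(a, 0) + 1
        return counts

    def n_distinct_called(self) -> int:
        return len(self.called_allele_counts())

    @property
    def is_biallelic(self) -> bool:
        return self.n_distinct_called() == 2

    @property
    def is_multiallelic(self) -> bool:
        return self.n_distinct_called() > 2

    @property
    def is_invariant(self) -> bool:
        return self.n_distinct_called() == 1

    def missing_count(self) -> int:
        """Number of genotypes with at least one missing allele."""
        return sum(1 for gt in self.genotypes if gt.is_missing)

    def minor_allele_frequency(self) -> float:
        """Frequency of the least frequent called allele (0.0 if invariant)."""
        counts = self.called_allele_counts()
        if len(counts) < 2:
            return 0.0
        total = sum(counts.values())
        return min(counts.values()) / total

    def minor_allele_count(self) -> int:
        counts = self.called_allele_counts()
        if len(counts) < 2:
            return 0
        return min(counts.values())


@dataclass
class VariantTable:
    samples: list[str]
    records: list[VariantRecord] = field(default_factory=list)
    header_meta: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rec in self.records:
            if len(rec.genotypes) != len(self.samples):
                raise ValueError(
                    f"record {rec.chrom}:{rec.pos} has {len(rec.genotypes)} genotypes "
                    f"for {len(self.samples)} samples"
                )

    def __len__(self) -> int:
        return len(self.records)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in table") from None

    def subset_samples(self, keep: Sequence[str]) -> "VariantTable":
        idx = [self.sample_index(s) for s in keep]
        records = [
            replace(rec, genotypes=[rec.genotypes[i] for i in idx]) for rec in self.records
        ]
        return VariantTable(list(keep), records, list(self.header_meta))

    def records_in(self, region: GenomicInterval) -> list[VariantRecord]:
        return [
            r
            for r in self.records
            if r.chrom == region.chrom and region.contains_pos(r.pos)
        ]

    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for rec in self.records:
            if rec.chrom not in seen:
                seen.append(rec.chrom)
        return seen

    def contig_order(self) -> list[str]:
        """Chromosome order from ##contig header lines, else first appearance."""
        order = []
        for line in self.header_meta:
            if line.startswith("##contig=") and "ID=" in line:
                ident = line.split("ID=")[1].split(",")[0].rstrip(">")
                order.append(ident)
        return order or self.chromosomes()


# -- file I/O -----------------------------------------------------------------


def _info_to_dict(rec: "pysam.VariantRecord") -> dict:
    out: dict = {}
    for key, val in rec.info.items():
        if val is True:
            out[key] = True
        elif isinstance(val, tuple):
            out[key] = ",".join(str(v) for v in val)
        else:
            out[key] = str(val)
    return out


def read_vcf(path) -> VariantTable:
    """Read plain or bgzip VCF text into a :class:`VariantTable`."""
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        header_meta = [
            line for line in str(vf.header).splitlines() if line.startswith("##")
        ]
        records: list[VariantRecord] = []
        for rec in vf:
            genotypes = []
            for s in samples:
                call = rec.samples[s]
                alleles = tuple(call.allele_indices) if call.allele_indices else (None,)
                genotypes.append(Genotype(alleles=alleles, phased=bool(call.phased)))
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts) if rec.alts else (),
                    id=rec.id,
                    qual=rec.qual,
                    filter=tuple(rec.filter.keys()),
                    info=_info_to_dict(rec),
                    genotypes=genotypes,
                )
            )
    return VariantTable(samples, records, header_meta)


def _format_info(info: dict) -> str:
    if not info:
        return "."
    parts = []
    for key, val in info.items():
        parts.append(key if val is True else f"{key}={val}")
    return ";".join(parts)


def _format_qual(q: float | None) -> str:
    if q is None:
        return "."
    return f"{q:g}"


def write_vcf(table: VariantTable, path) -> None:
    """Write VCF v4.x text; header ``##`` lines are re-emitted verbatim."""
    lines = list(table.header_meta)
    if not any(l.startswith("##fileformat") for l in lines):
        lines.insert(0, "##fileformat=VCFv4.2")
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if table.samples:
        cols += ["FORMAT"] + list(table.samples)
    lines.append("\t".join(cols))
    for rec in table.records:
        fields = [
            rec.chrom,
            str(rec.pos),
            rec.id or ".",
            rec.ref,
            ",".join(rec.alts) if rec.alts else ".",
            _format_qual(rec.qual),
            ";".join(rec.filter) if rec.filter else ".",
            _format_info(rec.info),
        ]
        if table.samples:
            fields += ["GT"] + [str(gt) for gt in rec.genotypes]
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# -- site filtering -----------------------------------------------------------

_CLASSES = {"biallelic", "multiallelic", "invariant"}


@dataclass
class SiteFilterSpec:
    """All-of-these site filter; ``None`` disables a criterion."""

    include_classes: frozenset[str] | None = None
    exclude_classes: frozenset[str] = frozenset()
    include_regions: Sequence[GenomicInterval] | None = None
    exclude_regions: Sequence[GenomicInterval] = ()
    max_missing_count: int | None = None
    max_missing_frac: float | None = None
    min_maf: float | None = None
    max_maf: float | None = None
    min_mac: int | None = None
    max_mac: int | None = None
    drop_indels: bool = False
    include_ids: frozenset[str] | None = None
    exclude_ids: frozenset[str] = frozenset()
    require_filter: str | None = None
    samples: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.include_classes is not None:
            self.include_classes = frozenset(self.include_classes)
            if not self.include_classes <= _CLASSES:
                raise ValueError(f"unknown allele classes {self.include_classes - _CLASSES}")
        self.exclude_classes = frozenset(self.exclude_classes)
        if not self.exclude_classes <= _CLASSES:
            raise ValueError(f"unknown allele classes {self.exclude_classes - _CLASSES}")
        if self.include_classes is not None and self.include_classes & self.exclude_classes:
            raise ValueError("allele-class include and exclude sets overlap")
        for bound in (self.min_maf, self.max_maf):
            if bound is not None and not (0.0 <= bound <= 0.5):
                raise ValueError(f"MAF bound {bound} outside [0, 0.5]")
        for bound in (self.min_mac, self.max_mac):
            if bound is not None and bound < 0:
                raise ValueError("MAC bounds must be >= 0")
        if self.include_ids is not None:
            self.include_ids = frozenset(self.include_ids)
            if self.include_ids & frozenset(self.exclude_ids):
                raise ValueError("ID include and exclude sets overlap")
        self.exclude_ids = frozenset(self.exclude_ids)


def _classify(rec: VariantRecord) -> str | None:
    k = rec.n_distinct_called()
    if k == 1:
        return "invariant"
    if k == 2:
        return "biallelic"
    if k > 2:
        return "multiallelic"
    return None  # no called alleles at all


def _in_any(rec: VariantRecord, regions: Sequence[GenomicInterval]) -> bool:
    return any(r.chrom == rec.chrom and r.contains_pos(rec.pos) for r in regions)


def _passes(rec: VariantRecord, spec: SiteFilterSpec) -> bool:
    cls = _classify(rec)
    if spec.include_classes is not None and cls not in spec.include_classes:
        return False
    if cls in spec.exclude_classes:
        return False
    if spec.include_regions is not None and not _in_any(rec, spec.include_regions):
        return False
    if spec.exclude_regions and _in_any(rec, spec.exclude_regions):
        return False
    miss = rec.missing_count()
    if spec.max_missing_count is not None and miss > spec.max_missing_count:
        return False
    if spec.max_missing_frac is not None and len(rec.genotypes):
        if miss / len(rec.genotypes) > spec.max_missing_frac:
            return False
    if spec.min_maf is not None and rec.minor_allele_frequency() < spec.min_maf:
        return False
    if spec.max_maf is not None and rec.minor_allele_frequency() > spec.max_maf:
        return False
    if spec.min_mac is not None and rec.minor_allele_count() < spec.min_mac:
        return False
    if spec.max_mac is not None and rec.minor_allele_count() > spec.max_mac:
        return False
    if spec.drop_indels and rec.is_indel:
        return False
    if spec.include_ids is not None and (rec.id or "") not in spec.include_ids:
        return False
    if rec.id is not None and rec.id in spec.exclude_ids:
        return False
    if spec.require_filter is not None and rec.filter != (spec.require_filter,):
        return False
    return True


def filter_sites(table: VariantTable, spec: SiteFilterSpec) -> VariantTable:
    """Keep exactly the records satisfying every active filter, in input order.

    If ``spec.samples`` is set the table is first restricted to that subset
    and all frequency/missingness criteria are evaluated on the retained
    samples only.  Idempotent: filtering a filtered table is a no-op.
    """
    if spec.samples is not None:
        table = table.subset_samples(spec.samples)
    kept = [rec for rec in table.records if _passes(rec, spec)]
    return VariantTable(list(table.samples), kept, list(table.header_meta))


# -- locus (BED-driven) filtering ---------------------------------------------


@dataclass
class LocusFilterSpec:
    """Informativeness thresholds for whole loci."""

    min_variants: int = 0
    max_missing: int | None = None
    min_length: int = 1
    ignore_indels: bool = False
    ignore_multiallelic: bool = False
    ignore_cpg: bool = False
    missing_per_site: bool = False  # count sites with any missing instead of genotypes

    def __post_init__(self) -> None:
        if self.min_variants < 0:
            raise ValueError("min_variants must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


def is_cpg_site(ref_seq: str, pos: int) -> bool:
    """Whether 1-based ``pos`` sits in a CG dinucleotide of ``ref_seq``.

    True when bases (pos, pos+1) or (pos-1, pos) spell CG — the symmetric
    rule covering both strands.
    """
    i = pos - 1
    seq = ref_seq.upper()
    if i + 1 < len(seq) and seq[i : i + 2] == "CG":
        return True
    if i >= 1 and seq[i - 1 : i + 1] == "CG":
        return True
    return False


def filter_loci(
    vcf: VariantTable,
    loci: Sequence[GenomicInterval],
    spec: LocusFilterSpec,
    ref: dict[str, str] | None = None,
) -> list[GenomicInterval]:
    """Keep loci with enough qualifying variants, little enough missing data,
    and sufficient length.

    A record qualifies as a variant when it is polymorphic among called
    genotypes and is not screened out by the ignore-indel / ignore-
    multiallelic / ignore-CpG switches.  ``ref`` (chrom → sequence) is
    required when ``ignore_cpg`` is set.
    """
    if spec.ignore_cpg and ref is None:
        raise ValueError("ignore_cpg requires a reference sequence")
    out = []
    for locus in loci:
        if ref is not None:
            if locus.chrom not in ref:
                raise KeyError(f"chromosome {locus.chrom!r} not in reference")
            if locus.end > len(ref[locus.chrom]):
                raise ValueError(f"locus {locus.chrom}:{locus.start}-{locus.end} beyond reference")
        if len(locus) < spec.min_length:
            continue
        recs = vcf.records_in(locus)
        n_var = 0
        n_missing = 0
        for rec in recs:
            if rec.missing_count():
                n_missing += 1 if spec.missing_per_site else rec.missing_count()
            if rec.n_distinct_called() < 2:
                continue
            if spec.ignore_indels and rec.is_indel:
                continue
            if spec.ignore_multiallelic and rec.is_multiallelic:
                continue
            if spec.ignore_cpg and is_cpg_site(ref[rec.chrom], rec.pos):
                continue
            n_var += 1
        if n_var < spec.min_variants:
            continue
        if spec.max_missing is not None and n_missing > spec.max_missing:
            continue
        out.append(locus)
    return out


# -- splitting and utilities --------------------------------------------------


def split_by_loci(
    vcf: VariantTable, loci: Sequence[GenomicInterval]
) -> list[tuple[GenomicInterval, VariantTable]]:
    """One (interval, table) pair per locus; header and samples are kept.

    Overlapping loci are permitted with a warning (records then appear in
    more than one output table).
    """
    if not loci:
        raise ValueError("empty locus list")
    ordered = sorted(loci, key=lambda iv: (iv.chrom, iv.start, iv.end))
    for prev, nxt in zip(ordered, ordered[1:]):
        if prev.chrom == nxt.chrom and nxt.start < prev.end:
            warnings.warn("overlapping loci: records may be duplicated across outputs")
            break
    return [
        (locus, VariantTable(list(vcf.samples), vcf.records_in(locus), list(vcf.header_meta)))
        for locus in loci
    ]


def concat_vcfs(tables: Sequence[VariantTable]) -> VariantTable:
    if not tables:
        raise ValueError("no tables to concatenate")
    samples = tables[0].samples
    for t in tables[1:]:
        if t.samples != samples:
            raise ValueError("concat requires identical sample lists")
    records = [rec for t in tables for rec in t.records]
    return VariantTable(list(samples), records, list(tables[0].header_meta))


def merge_vcfs(tables: Sequence[VariantTable]) -> VariantTable:
    """Site-wise merge keyed on (chrom, pos, ref); absent genotypes become missing.

    Sample sets must be disjoint or consistent: a sample present in several
    tables must make the same call wherever the site is shared.
    """
    if not tables:
        raise ValueError("no tables to merge")
    samples: list[str] = []
    for t in tables:
        for s in t.samples:
            if s not in samples:
                samples.append(s)

    sites: dict[tuple[str, int], dict] = {}
    order: list[tuple[str, int]] = []
    for t in tables:
        for rec in t.records:
            key = (rec.chrom, rec.pos)
            if key not in sites:
                sites[key] = {
                    "ref": rec.ref,
                    "alts": list(rec.alts),
                    "id": rec.id,
                    "qual": rec.qual,
                    "filter": rec.filter,
                    "info": dict(rec.info),
                    "calls": {},
                }
                order.append(key)
            site = sites[key]
            if site["ref"] != rec.ref:
                raise ValueError(f"conflicting REF at {rec.chrom}:{rec.pos}")
            # remap this table's allele indices onto the merged allele list
            remap: dict[int, int] = {0: 0}
            for i, alt in enumerate(rec.alts, start=1):
                if alt not in site["alts"]:
                    site["alts"].append(alt)
                remap[i] = site["alts"].index(alt) + 1
            for s, gt in zip(t.samples, rec.genotypes):
                mapped = Genotype(
                    tuple(None if a is None else remap[a] for a in gt.alleles),
                    gt.phased,
                )
                if s in site["calls"] and site["calls"][s] != mapped:
                    raise ValueError(
                        f"conflicting call for sample {s!r} at {rec.chrom}:{rec.pos}"
                    )
                site["calls"][s] = mapped

    ploidy = max(
        (len(gt.alleles) for t in tables for r in t.records for gt in r.genotypes),
        default=2,
    )
    missing = Genotype(tuple([None] * ploidy), False)
    records = []
    for key in order:
        site = sites[key]
        records.append(
            VariantRecord(
                chrom=key[0],
                pos=key[1],
                ref=site["ref"],
                alts=tuple(site["alts"]),
                id=site["id"],
                qual=site["qual"],
                filter=site["filter"],
                info=site["info"],
                genotypes=[site["calls"].get(s, missing) for s in samples],
            )
        )
    merged = VariantTable(samples, records, list(tables[0].header_meta))
    return sort_vcf(merged)


def sort_vcf(table: VariantTable) -> VariantTable:
    """Stable sort by (header contig order, pos); idempotent."""
    chrom_order = {c: i for i, c in enumerate(table.contig_order())}
    n = len(chrom_order)
    records = sorted(
        table.records, key=lambda r: (chrom_order.get(r.chrom, n), r.chrom, r.pos)
    )
    return VariantTable(list(table.samples), records, list(table.header_meta))


def list_chromosomes(table: VariantTable) -> list[str]:
    return table.chromosomes()


def list_samples(table: VariantTable) -> list[str]:
    return list(table.samples)
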