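"""Per-haplotype sequence reconstruction from reference FASTA + phased VCF.

Each haplotype of each model individual is rebuilt over a BED region by
substituting, at every SNP position, the allele that haplotype carries into
the reference substring.  Positions without a variant record stay at the
reference base; missing alleles become ``N`` so absent data stays visible
downstream.  Loci containing indels are rejected by default so that all
sequences of a locus have equal length — the substrate the IMa3 and G-PhoCS
exporters require.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

from Bio import SeqIO

from .bed import GenomicInterval
from .model_io import PopulationModel
from .vcf import VariantTable

__all__ = ["Haplotype", "LocusAlignment", "read_fasta", "reconstruct_sequences", "write_fasta"]


def read_fasta(path) -> dict[str, str]:
    """chrom → uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


@dataclass(frozen=True)
class Haplotype:
    individual: str
    index: int  # 1-based haplotype number within the individual
    sequence: str

    @property
    def name(self) -> str:
        return f"{self.individual}_{self.index}"


@dataclass
class LocusAlignment:
    """Equal-length haplotype sequences for one region, in model order."""

    name: str
    region: GenomicInterval
    haplotypes: list[Haplotype]
    pop_counts: dict[str, int]  # haploid sequence count per population

    def __post_init__(self) -> None:
        L = len(self.region)
        for hap in self.haplotypes:
            if len(hap.sequence) != L:
                raise ValueError(
                    f"haplotype {hap.name} length {len(hap.sequence)} != region length {L}"
                )
            if not set(hap.sequence) <= set("ACGTN"):
                raise ValueError(f"haplotype {hap.name} has non-ACGTN characters")
        if sum(self.pop_counts.values()) != len(self.haplotypes):
            raise ValueError("population counts do not sum to the haplotype count")

    @property
    def length(self) -> int:
        return len(self.region)


def reconstruct_sequences(
    ref: dict[str, str],
    vcf: VariantTable,
    region: GenomicInterval,
    model: PopulationModel,
    name: str | None = None,
    on_indel: Literal["error", "skip"] = "error",
) -> LocusAlignment:
    """Build the per-haplotype alignment of ``region`` for all model individuals.

    Heterozygous genotypes inside the region must be phased.  Indel records
    overlapping the region raise by default (``on_indel="skip"`` drops them
    with a warning instead, keeping the alignment rectangular).
    """
    if region.chrom not in ref:
        raise KeyError(f"chromosome {region.chrom!r} not in reference")
    chrom_seq = ref[region.chrom]
    if region.end > len(chrom_seq):
        raise ValueError(f"region {region.chrom}:{region.start}-{region.end} beyond reference")
    base = chrom_seq[region.start : region.end]

    records = []
    for rec in vcf.records_in(region):
        if rec.is_indel:
            if on_indel == "error":
                raise ValueError(f"indel at {rec.chrom}:{rec.pos} overlaps the region")
            warnings.warn(f"skipping indel at {rec.chrom}:{rec.pos}")
            continue
        records.append(rec)

    sample_idx = {s: i for i, s in enumerate(vcf.samples)}
    ploidy = max((len(g.alleles) for r in records for g in r.genotypes), default=2)

    haplotypes: list[Haplotype] = []
    pop_counts: dict[str, int] = {}
    for pop, inds in model.pops.items():
        pop_counts[pop] = 0
        for ind in inds:
            if ind not in sample_idx:
                raise KeyError(f"individual {ind!r} not in the variant table")
            col = sample_idx[ind]
            for k in range(ploidy):
                seq = list(base)
                for rec in records:
                    gt = rec.genotypes[col]
                    if gt.is_het and not gt.phased:
                        raise ValueError(
                            f"unphased heterozygote for {ind} at {rec.chrom}:{rec.pos}"
                        )
                    allele = gt.alleles[k] if k < len(gt.alleles) else None
                    offset = rec.pos - 1 - region.start
                    seq[offset] = "N" if allele is None else rec.alleles[allele]
                haplotypes.append(Haplotype(ind, k + 1, "".join(seq)))
                pop_counts[pop] += 1
    return LocusAlignment(
        name=name or f"{region.chrom}_{region.start}_{region.end}",
        region=region,
        haplotypes=haplotypes,
        pop_counts=pop_counts,
    )


def write_fasta(alignment: LocusAlignment, path) -> None:
    with open(path, "w") as fh:
        for hap in alignment.haplotypes:
            fh.write(f">{hap.name}\n{hap.sequence}\n")
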