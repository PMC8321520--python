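"""End-to-end workflow: filtered VCF → informative loci → sampled loci →
per-locus tables → four-gamete blocks → reconstructed sequences → IM file.

This chains the individual modules exactly the way a multi-locus
isolation-with-migration study prepares its input: site filtering first,
then locus informativeness filtering against a BED of candidate regions,
statistic-guided subsampling, per-locus splitting, four-gamete extraction
of a recombination-free block per locus, sequence reconstruction, and a
single IM-format output file.  Loci where no compatible block meets the
minimum site count are dropped, mirroring pipeline filtering semantics.
"""

from __future__ import annotations

from dataclasses import dataclass

from .bed import GenomicInterval
from .four_gamete import HaplotypeMatrix, LocusRejected, extract_block, find_compatible_intervals
from .model_io import PopulationModel
from .seqs import LocusAlignment, reconstruct_sequences
from .stats import WindowStat, sample_loci, tajimas_d
from .vcf import LocusFilterSpec, SiteFilterSpec, VariantTable, filter_loci, filter_sites, split_by_loci
from .writers import write_ima


@dataclass
class PipelineResult:
    n_input_records: int
    n_filtered_records: int
    n_informative_loci: int
    n_sampled_loci: int
    n_surviving_loci: int
    loci: list[LocusAlignment]
    ima_path: str | None


def run_im_pipeline(
    vcf: VariantTable,
    reference: dict[str, str],
    loci: list[GenomicInterval],
    model: PopulationModel,
    site_spec: SiteFilterSpec | None = None,
    locus_spec: LocusFilterSpec | None = None,
    sample_n: int = 20,
    sample_bins: int = 2,
    min_block_sites: int = 2,
    seed: int = 0,
    ima_out: str | None = None,
) -> PipelineResult:
    """Run the full locus-preparation workflow and optionally write an IM file.

    Deterministic given ``seed``; loci are scored with Tajima's D for the
    uniform-bin subsampling step.
    """
    if site_spec is None:
        site_spec = SiteFilterSpec(
            include_classes=frozenset({"biallelic"}),
            max_missing_count=0,
            drop_indels=True,
            require_filter="PASS",
            samples=model.individuals(),
        )
    if locus_spec is None:
        locus_spec = LocusFilterSpec(min_variants=4, ignore_indels=True, ignore_multiallelic=True)

    filtered = filter_sites(vcf, site_spec)
    informative = filter_loci(filtered, loci, locus_spec, ref=reference)

    scored: list[WindowStat] = []
    by_key: dict[tuple[str, int, int], GenomicInterval] = {}
    for locus in informative:
        ws = tajimas_d(filtered, locus)
        scored.append(ws)
        by_key[(ws.chrom, ws.start, ws.end)] = locus
    sampled_stats = sample_loci(scored, "uniform", n=sample_n, bins=sample_bins, seed=seed)
    sampled = [by_key[(ws.chrom, ws.start, ws.end)] for ws in sampled_stats]

    alignments: list[LocusAlignment] = []
    for locus, (interval, sub) in zip(sampled, split_by_loci(filtered, sampled)):
        matrix = HaplotypeMatrix.from_table(sub)
        if matrix.n_sites == 0:
            continue
        intervals = find_compatible_intervals(matrix)
        try:
            block = extract_block(
                sub, intervals, mode="single", selection="longest", min_sites=min_block_sites
            )[0]
        except LocusRejected:
            continue
        lo = min(r.pos for r in block.records) - 1
        hi = max(r.pos for r in block.records)
        region = GenomicInterval(interval.chrom, lo, hi, name=interval.name)
        alignments.append(
            reconstruct_sequences(reference, block, region, model, name=interval.name or "locus")
        )

    if ima_out is not None and alignments:
        write_ima(alignments, model, ima_out)
    return PipelineResult(
        n_input_records=len(vcf),
        n_filtered_records=len(filtered),
        n_informative_loci=len(informative),
        n_sampled_loci=len(sampled),
        n_surviving_loci=len(alignments),
        loci=alignments,
        ima_path=str(ima_out) if ima_out is not None and alignments else None,
    )
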