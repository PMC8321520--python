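"""Model-aware export formats: IMa3, G-PhoCS, treemix, dadi, EIGENSTRAT, PED.

Sequence-based writers (IMa3, G-PhoCS) consume :class:`LocusAlignment`
objects from :mod:`popgencore.seqs`; genotype-based writers (treemix, dadi
SNP table, EIGENSTRAT, PED-12) consume a :class:`VariantTable` plus a
:class:`PopulationModel`.  Every declared count in an output file equals
the number of lines actually emitted.

IMa3 dialect notes: the sequence-name field is fixed-width (10 characters,
left-justified, space-padded, non-alphanumerics mapped to ``_``); each
locus header carries per-population haploid sample counts in model order,
the locus length, a one-letter mutation-model code and an inheritance
scalar.  The defaults (code ``I`` for infinite sites, scalar 1.0 for
autosomes) suit loci that were pre-filtered with the four-gamete test.
"""

from __future__ import annotations

import re
from typing import Sequence

from .model_io import PopulationModel
from .seqs import LocusAlignment
from .vcf import VariantTable

__all__ = [
    "sanitize_name",
    "write_ima",
    "write_gphocs",
    "write_treemix",
    "write_dadi_snp",
    "write_eigenstrat",
    "write_ped",
]


def sanitize_name(name: str, width: int = 10) -> str:
    """Map non-alphanumerics to '_' and truncate to ``width`` characters."""
    return re.sub(r"[^A-Za-z0-9_]", "_", name)[:width]


def _check_rectangular(locus: LocusAlignment) -> None:
    lengths = {len(h.sequence) for h in locus.haplotypes}
    if len(lengths) != 1:
        raise ValueError(f"locus {locus.name!r} has unequal sequence lengths")


# -- sequence formats ---------------------------------------------------------


def write_ima(
    loci: Sequence[LocusAlignment],
    model: PopulationModel,
    out,
    mutation_model: str = "I",
    inheritance: float = 1.0,
    title: str = "popgencore IM export",
) -> None:
    """Single IM-format file for IMa3: title, #pops, names, tree, #loci, loci."""
    if not loci:
        raise ValueError("empty locus list")
    if model.tree is None:
        raise ValueError("IMa3 export requires a population tree on the model")
    if model.n_pops < 2:
        raise ValueError("IMa3 export requires at least two populations")
    lines = [title, str(model.n_pops), " ".join(model.pop_names), model.tree, str(len(loci))]
    for locus in loci:
        _check_rectangular(locus)
        counts = [locus.pop_counts.get(pop, 0) for pop in model.pop_names]
        if sum(counts) != len(locus.haplotypes):
            raise ValueError(f"locus {locus.name!r}: population counts != sequences")
        header = " ".join(
            [sanitize_name(locus.name)]
            + [str(c) for c in counts]
            + [str(locus.length), mutation_model, f"{inheritance:g}"]
        )
        lines.append(header)
        for pop in model.pop_names:  # sequences grouped by population, model order
            for hap in locus.haplotypes:
                if model.population_of(hap.individual) == pop:
                    lines.append(f"{sanitize_name(hap.name):<10}{hap.sequence}")
    with open(out, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_gphocs(loci: Sequence[LocusAlignment], out) -> None:
    """G-PhoCS sequence file: locus count, then per-locus headers + sequences."""
    if not loci:
        raise ValueError("empty locus list")
    lines = [str(len(loci))]
    for locus in loci:
        _check_rectangular(locus)
        lines.append(f"{sanitize_name(locus.name)} {len(locus.haplotypes)} {locus.length}")
        for hap in locus.haplotypes:
            lines.append(f"{sanitize_name(hap.name)} {hap.sequence}")
    with open(out, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# -- genotype formats ---------------------------------------------------------


def _pop_columns(vcf: VariantTable, model: PopulationModel) -> dict[str, list[int]]:
    return {
        pop: [vcf.sample_index(ind) for ind in inds] for pop, inds in model.pops.items()
    }


def write_treemix(
    vcf: VariantTable,
    model: PopulationModel,
    out,
    drop_invariant: bool = False,
    strict: bool = False,
) -> dict[str, int]:
    """treemix allele-count file: header of population names, then one
    ``refCount,altCount`` block per population per biallelic site.

    Returns skip counters.  A site where some population has zero called
    alleles is skipped (``strict`` raises instead).
    """
    pop_cols = _pop_columns(vcf, model)
    skipped = {"not_biallelic": 0, "uncalled_pop": 0, "invariant": 0}
    lines = [" ".join(model.pop_names)]
    for rec in vcf.records:
        if len(rec.alts) != 1:
            skipped["not_biallelic"] += 1
            continue
        if drop_invariant and rec.n_distinct_called() < 2:
            skipped["invariant"] += 1
            continue
        fields = []
        ok = True
        for cols in pop_cols.values():
            ref = alt = 0
            for j in cols:
                for a in rec.genotypes[j].alleles:
                    if a == 0:
                        ref += 1
                    elif a == 1:
                        alt += 1
            if ref + alt == 0:
                if strict:
                    raise ValueError(f"no called alleles at {rec.chrom}:{rec.pos}")
                ok = False
                break
            fields.append(f"{ref},{alt}")
        if not ok:
            skipped["uncalled_pop"] += 1
            continue
        lines.append(" ".join(fields))
    with open(out, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return skipped


def _context(ref_seq: str | None, pos: int) -> str:
    """Reference trinucleotide around 1-based ``pos``, '-'-padded at edges."""
    if ref_seq is None:
        return "-X-"
    i = pos - 1
    left = ref_seq[i - 1] if i >= 1 else "-"
    mid = ref_seq[i]
    right = ref_seq[i + 1] if i + 1 < len(ref_seq) else "-"
    return f"{left}{mid}{right}"


def write_dadi_snp(
    vcf: VariantTable,
    model: PopulationModel,
    out,
    ref: dict[str, str] | None = None,
    outgroup: str | None = None,
) -> int:
    """dadi SNP-format table; returns the number of sites written.

    One row per biallelic site: ingroup context, outgroup context, REF
    allele with per-population counts, ALT allele with per-population
    counts, locus (chromosome) and position.  The outgroup context carries
    the named outgroup individual's allele at the site centre; ``---`` when
    no outgroup is given.
    """
    pop_cols = _pop_columns(vcf, model)
    og_col = vcf.sample_index(outgroup) if outgroup is not None else None
    header = (
        ["Ingroup", "Outgroup", "Allele1"]
        + model.pop_names
        + ["Allele2"]
        + model.pop_names
        + ["Gene", "Position"]
    )
    lines = ["\t".join(header)]
    written = 0
    for rec in vcf.records:
        if len(rec.alts) != 1 or rec.is_indel:
            continue
        chrom_seq = ref.get(rec.chrom) if ref else None
        ingroup = _context(chrom_seq, rec.pos)
        if og_col is None:
            outg = "---"
        else:
            a = rec.genotypes[og_col].alleles[0]
            centre = "-" if a is None else rec.alleles[a]
            outg = ingroup[0] + centre + ingroup[2] if chrom_seq else f"-{centre}-"
        refs, alts = [], []
        for cols in pop_cols.values():
            r = a_ = 0
            for j in cols:
                for al in rec.genotypes[j].alleles:
                    if al == 0:
                        r += 1
                    elif al == 1:
                        a_ += 1
            refs.append(str(r))
            alts.append(str(a_))
        lines.append(
            "\t".join(
                [ingroup, outg, rec.ref] + refs + [rec.alts[0]] + alts
                + [rec.chrom, str(rec.pos)]
            )
        )
        written += 1
    with open(out, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return written


def _check_diploid_biallelic(rec) -> None:
    if len(rec.alts) != 1:
        raise ValueError(f"multiallelic record at {rec.chrom}:{rec.pos}")
    for gt in rec.genotypes:
        if len(gt.alleles) != 2:
            raise ValueError(f"non-diploid genotype at {rec.chrom}:{rec.pos}")


def write_eigenstrat(vcf: VariantTable, model: PopulationModel, out_prefix) -> None:
    """EIGENSTRAT triple: .geno (counts of the REF allele, 9 = missing),
    .snp (id, chrom, genetic pos 0.0, physical pos, REF, ALT) and .ind
    (individual, sex U, population)."""
    inds = model.individuals()
    sub = vcf.subset_samples(inds)
    geno_lines, snp_lines = [], []
    for i, rec in enumerate(sub.records):
        _check_diploid_biallelic(rec)
        digits = []
        for gt in rec.genotypes:
            if gt.is_missing:
                digits.append("9")
            else:
                digits.append(str(sum(1 for a in gt.alleles if a == 0)))
        geno_lines.append("".join(digits))
        snp_id = rec.id or f"snp_{i + 1}"
        snp_lines.append(
            f"{snp_id}\t{rec.chrom}\t0.0\t{rec.pos}\t{rec.ref}\t{rec.alts[0]}"
        )
    ind_lines = [f"{ind}\tU\t{model.population_of(ind)}" for ind in inds]
    for suffix, lines in ((".geno", geno_lines), (".snp", snp_lines), (".ind", ind_lines)):
        with open(f"{out_prefix}{suffix}", "w") as fh:
            fh.write("\n".join(lines) + "\n")


def write_ped(vcf: VariantTable, model: PopulationModel, out_prefix) -> None:
    """PED-12 (.ped/.map): alleles coded REF=1, ALT=2, missing=0 0."""
    inds = model.individuals()
    sub = vcf.subset_samples(inds)
    for rec in sub.records:
        _check_diploid_biallelic(rec)
    with open(f"{out_prefix}.map", "w") as fh:
        for i, rec in enumerate(sub.records):
            fh.write(f"{rec.chrom}\t{rec.id or f'snp_{i + 1}'}\t0\t{rec.pos}\n")
    with open(f"{out_prefix}.ped", "w") as fh:
        for col, ind in enumerate(inds):
            fields = [model.population_of(ind), ind, "0", "0", "0", "-9"]
            for rec in sub.records:
                gt = rec.genotypes[col]
                for a in gt.alleles:
                    fields.append("0" if a is None else str(a + 1))
            fh.write("\t".join(fields) + "\n")
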