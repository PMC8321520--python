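"""Synthetic reference + phased VCF + BED + model fixtures with known truth.

Every generator here is deterministic from a mandatory seed (numpy PCG64)
and returns, alongside the data, a *truth record* of what was planted —
indel/multiallelic/missing/flag-fail record counts, CpG-context positions,
recombination-free block boundaries, the expected FST of the island model —
so filtering, four-gamete and statistics tests have exact expectations
without any external download.

Allele-frequency structure
--------------------------
``shared`` draws one frequency per site used by every population;
``island`` draws an ancestral frequency and then per-population frequencies
from the Balding–Nichols beta distribution
``Beta(p(1-F)/F, (1-p)(1-F)/F)``, whose among-population differentiation
has expectation F — the truth record stores F as the oracle expected FST.

Recombination-free blocks
-------------------------
Haplotypes inside one block are mutations on a random perfect genealogy:
each site's derived set is a clade of one random coalescent topology, so
any two within-block sites show at most three gametes by construction.
Across a block boundary the first site of the new block is forced to
overlap partially (but not nest) with the last site of the previous block,
which displays all four gametes and plants an incompatibility exactly at
the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bed import GenomicInterval
from .model_io import ModelFile, PopulationModel, create_model
from .vcf import Genotype, VariantRecord, VariantTable

__all__ = [
    "SimulationSpec",
    "SimulatedData",
    "standard_header",
    "simulate_dataset",
    "simulate_block_matrix",
    "random_haplotype_matrix",
    "simulate_fst_window",
    "haplotypes_to_table",
]

_BASES = "ACGT"


def standard_header(chrom_lengths: dict[str, int]) -> list[str]:
    lines = [
        "##fileformat=VCFv4.2",
        '##FILTER=<ID=PASS,Description="All filters passed">',
        '##FILTER=<ID=LowQual,Description="Low quality">',
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    lines += [f"##contig=<ID={c},length={l}>" for c, l in chrom_lengths.items()]
    return lines


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic dataset."""

    seed: int
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 250_000})
    populations: dict[str, int] = field(default_factory=lambda: {"CT": 4, "WC": 3})
    ploidy: int = 2
    freq_model: str = "island"  # "island" | "shared"
    fst: float = 0.1
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    n_loci: int = 100
    locus_length: int = 1000
    snps_per_locus_mean: float = 10.0
    n_indels: int = 5
    n_multiallelic: int = 3
    n_missing: int = 4
    n_fail_filter: int = 3
    n_cpg: int = 5

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("at least one population required")
        if any(l < 1 for l in self.chrom_lengths.values()) or not self.chrom_lengths:
            raise ValueError("chromosome lengths must be >= 1")
        if not (0.0 < self.fst < 1.0):
            raise ValueError("target FST must lie in (0, 1)")


@dataclass
class SimulatedData:
    reference: dict[str, str]
    vcf: VariantTable
    loci: list[GenomicInterval]
    models: ModelFile
    truth: dict


def _nested_tree(pop_names: list[str]) -> str:
    tree = pop_names[0]
    for name in pop_names[1:]:
        tree = f"({tree},{name})"
    return tree


def _pop_frequencies(rng, spec: SimulationSpec) -> list[float]:
    lo, hi = spec.ancestral_freq_range
    p = rng.uniform(lo, hi)
    if spec.freq_model == "shared":
        return [p] * len(spec.populations)
    F = spec.fst
    a, b = p * (1 - F) / F, (1 - p) * (1 - F) / F
    return [float(np.clip(rng.beta(a, b), 0.0, 1.0)) for _ in spec.populations]


def _draw_genotypes(
    rng, spec: SimulationSpec, freqs: list[float], alt_index: int = 1
) -> list[Genotype]:
    gts = []
    for f in zip(spec.populations.values(), freqs):
        n_ind, p = f
        for _ in range(n_ind):
            alleles = tuple(
                alt_index if rng.random() < p else 0 for _ in range(spec.ploidy)
            )
            gts.append(Genotype(alleles=alleles, phased=True))
    return gts


def simulate_dataset(spec: SimulationSpec) -> SimulatedData:
    """Reference FASTA + phased VCF + BED loci + model file + truth record.

    Variant positions are laid on a 3-bp grid inside the loci so that
    planted CpG contexts (and their deliberate absence elsewhere) never
    collide with neighbouring records.  Byte-identical output for a given
    spec.
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    ref = {
        chrom: list(rng.choice(list(_BASES), size=length))
        for chrom, length in spec.chrom_lengths.items()
    }

    # non-overlapping loci, tiled with a one-locus gap
    loci: list[GenomicInterval] = []
    per_chrom_capacity = {
        c: max(0, (l - 10) // (2 * spec.locus_length)) for c, l in spec.chrom_lengths.items()
    }
    remaining = spec.n_loci
    for chrom, cap in per_chrom_capacity.items():
        take = min(cap, remaining)
        for i in range(take):
            start = 5 + i * 2 * spec.locus_length
            loci.append(GenomicInterval(chrom, start, start + spec.locus_length, name=f"L{len(loci)}"))
        remaining -= take
    if remaining > 0:
        raise ValueError("chromosomes too short for the requested loci")

    # candidate variant positions (1-based), 3-bp spacing inside loci
    positions: list[tuple[str, int, int]] = []  # (chrom, pos, locus_index)
    for li, locus in enumerate(loci):
        grid = np.arange(locus.start + 3, locus.end - 1, 3)
        k = min(len(grid), rng.poisson(spec.snps_per_locus_mean))
        if k == 0:
            continue
        chosen = np.sort(rng.choice(grid, size=k, replace=False))
        positions.extend((locus.chrom, int(p) + 1, li) for p in chosen)

    n_special = spec.n_indels + spec.n_multiallelic + spec.n_missing + spec.n_fail_filter + spec.n_cpg
    if len(positions) < n_special + 1:
        raise ValueError("too few variant positions for the requested planted records")
    special_idx = rng.choice(len(positions), size=n_special, replace=False)
    cursor = 0
    roles: dict[int, str] = {}
    for role, count in (
        ("indel", spec.n_indels),
        ("multiallelic", spec.n_multiallelic),
        ("missing", spec.n_missing),
        ("fail_filter", spec.n_fail_filter),
        ("cpg", spec.n_cpg),
    ):
        for idx in special_idx[cursor : cursor + count]:
            roles[int(idx)] = role
        cursor += count

    records: list[VariantRecord] = []
    truth: dict = {
        "n_records": len(positions),
        "n_indels": spec.n_indels,
        "n_multiallelic": spec.n_multiallelic,
        "n_missing": spec.n_missing,
        "n_fail_filter": spec.n_fail_filter,
        "cpg_positions": [],
        "expected_fst": spec.fst if spec.freq_model == "island" else 0.0,
        "locus_records": [[] for _ in loci],  # (pos, role) per locus
    }
    n_hap = spec.ploidy * sum(spec.populations.values())
    for idx, (chrom, pos, li) in enumerate(positions):
        i = pos - 1  # 0-based
        role = roles.get(idx, "clean")
        seq = ref[chrom]
        if role == "cpg":
            seq[i], seq[i + 1] = "C", "G"
            truth["cpg_positions"].append((chrom, pos))
        else:
            # break any accidental CpG context around a variant position
            if seq[i] == "C" and seq[i + 1] == "G":
                seq[i + 1] = "A"
            if i >= 1 and seq[i - 1] == "C" and seq[i] == "G":
                seq[i - 1] = "A"
        ref_base = seq[i]
        alt_base = rng.choice([b for b in _BASES if b != ref_base])
        freqs = _pop_frequencies(rng, spec)
        gts = _draw_genotypes(rng, spec, freqs)
        # clean/cpg/missing/fail records must segregate so truth counts are
        # exact; the missing-role record keeps sample 0 free to blank out
        if role in ("clean", "cpg", "missing", "fail_filter"):
            fix = 1 if role == "missing" else 0
            carried = {
                a
                for k, g in enumerate(gts)
                for a in g.alleles
                if not (role == "missing" and k == 0)
            }
            if carried == {0}:
                gts[fix] = Genotype((1,) + gts[fix].alleles[1:], True)
            elif carried == {1}:
                gts[fix] = Genotype((0,) + gts[fix].alleles[1:], True)
        rec_kwargs = dict(
            chrom=chrom,
            pos=pos,
            ref=ref_base,
            alts=(str(alt_base),),
            qual=50.0,
            filter=("PASS",),
            info={"AA": ref_base},
        )
        if role == "indel":
            rec_kwargs["ref"] = ref_base + seq[i + 1]
        elif role == "multiallelic":
            alt2 = rng.choice([b for b in _BASES if b not in (ref_base, alt_base)])
            rec_kwargs["alts"] = (str(alt_base), str(alt2))
            gts[0] = Genotype((0, 1), True)
            gts[1] = Genotype((1, 2), True)
        elif role == "missing":
            gts[0] = Genotype((None,) * spec.ploidy, False)
        elif role == "fail_filter":
            rec_kwargs["filter"] = ("LowQual",)
        records.append(VariantRecord(genotypes=gts, **rec_kwargs))
        truth["locus_records"][li].append((pos, role))

    individuals = {
        pop: [f"{pop}_{k + 1}" for k in range(n)] for pop, n in spec.populations.items()
    }
    model = create_model("main", individuals, tree=_nested_tree(list(spec.populations)))
    models = ModelFile()
    models.add(model)
    samples = model.individuals()
    table = VariantTable(samples, records, standard_header(spec.chrom_lengths))
    truth["n_clean_biallelic"] = sum(
        1
        for idx in range(len(positions))
        if roles.get(idx, "clean") in ("clean", "cpg")
    )
    return SimulatedData(
        reference={c: "".join(s) for c, s in ref.items()},
        vcf=table,
        loci=loci,
        models=models,
        truth=truth,
    )


# -- four-gamete substrates ---------------------------------------------------


def _random_clades(rng, labels: list[int], first_merge: tuple[int, int] | None):
    """Clades of a random coalescent topology over ``labels``.

    Returns every proper clade (singletons included, root excluded).  When
    ``first_merge`` is given, that pair coalesces first and is therefore a
    clade.
    """
    groups = [frozenset([x]) for x in labels]
    clades = list(groups)
    if first_merge is not None:
        a, b = first_merge
        groups = [g for g in groups if g not in (frozenset([a]), frozenset([b]))]
        groups.append(frozenset([a, b]))
        clades.append(frozenset([a, b]))
    while len(groups) > 1:
        i, j = rng.choice(len(groups), size=2, replace=False)
        merged = groups[i] | groups[j]
        groups = [g for k, g in enumerate(groups) if k not in (i, j)]
        groups.append(merged)
        if len(groups) > 1:  # exclude the root (all-derived is not segregating)
            clades.append(merged)
    return clades


def simulate_block_matrix(
    n_haplotypes: int, block_sites: list[int], seed: int, start_pos: int = 1, spacing: int = 10
) -> tuple[np.ndarray, list[int], list[tuple[int, int]]]:
    """0/1 haplotype matrix made of recombination-free blocks.

    Returns (matrix of shape n_haplotypes x n_sites, 1-based positions,
    truth block index ranges [start, end] inclusive).  Within a block every
    site pair is four-gamete compatible by construction; each pair of sites
    straddling a block boundary's planted columns is incompatible, so the
    maximal compatible intervals are exactly the blocks.
    """
    if n_haplotypes < 4:
        raise ValueError("block planting requires >= 4 haplotypes")
    if not block_sites or any(m < 1 for m in block_sites):
        raise ValueError("each block needs >= 1 site")
    rng = np.random.Generator(np.random.PCG64(seed))
    labels = list(range(n_haplotypes))
    cols: list[np.ndarray] = []
    blocks: list[tuple[int, int]] = []
    prev_last: frozenset | None = None
    for m in block_sites:
        if prev_last is None:
            clades = _random_clades(rng, labels, first_merge=None)
            forced_first = None
        else:
            inside = sorted(prev_last)
            outside = sorted(set(labels) - prev_last)
            pair = (inside[int(rng.integers(len(inside)))], outside[int(rng.integers(len(outside)))])
            clades = _random_clades(rng, labels, first_merge=pair)
            forced_first = frozenset(pair)
        # pick this block's derived sets; pin the boundary columns
        two_clades = [c for c in clades if 2 <= len(c) <= n_haplotypes - 2]
        last_set = two_clades[int(rng.integers(len(two_clades)))]
        sets = []
        for k in range(m):
            if k == 0 and forced_first is not None:
                sets.append(forced_first)
            elif k == m - 1 and m > 1:
                sets.append(last_set)
            else:
                sets.append(clades[int(rng.integers(len(clades)))])
        if m == 1 and forced_first is None:
            sets = [last_set]
        elif m == 1:
            # the single column is both boundary partner and block content;
            # forced_first (size 2, partial overlap with prev_last) also has
            # 2 <= size <= n-2, so the next boundary stays plantable
            sets = [forced_first]
        start = len(cols)
        for s in sets:
            col = np.zeros(n_haplotypes, dtype=np.int8)
            col[list(s)] = 1
            cols.append(col)
        blocks.append((start, len(cols) - 1))
        prev_last = sets[-1]
    matrix = np.stack(cols, axis=1)
    positions = [start_pos + i * spacing for i in range(matrix.shape[1])]
    return matrix, positions, blocks


def random_haplotype_matrix(
    n_haplotypes: int, n_sites: int, seed: int, missing_rate: float = 0.0
) -> tuple[np.ndarray, list[int]]:
    """Random segregating 0/1 matrix (with optional missing = -1 entries)."""
    rng = np.random.Generator(np.random.PCG64(seed))
    matrix = np.zeros((n_haplotypes, n_sites), dtype=np.int8)
    for j in range(n_sites):
        while True:
            col = rng.integers(0, 2, size=n_haplotypes)
            if 0 < col.sum() < n_haplotypes:
                break
        matrix[:, j] = col
    if missing_rate > 0:
        mask = rng.random(matrix.shape) < missing_rate
        matrix[mask] = -1
    positions = [1 + 10 * i for i in range(n_sites)]
    return matrix, positions


def haplotypes_to_table(
    matrix: np.ndarray,
    positions: list[int],
    samples: list[str],
    chrom: str = "chr1",
    chrom_length: int | None = None,
    ploidy: int = 2,
) -> VariantTable:
    """Pack a 0/1/-1 haplotype matrix into a phased VariantTable.

    Row ``ploidy*i + k`` becomes haplotype k of ``samples[i]``.  REF/ALT are
    arbitrary A/T SNPs.
    """
    n_hap, n_sites = matrix.shape
    if n_hap != ploidy * len(samples):
        raise ValueError("matrix rows must equal ploidy * samples")
    if chrom_length is None:
        chrom_length = max(positions) + 100
    records = []
    for j in range(n_sites):
        gts = []
        for i in range(len(samples)):
            alleles = tuple(
                None if matrix[ploidy * i + k, j] < 0 else int(matrix[ploidy * i + k, j])
                for k in range(ploidy)
            )
            gts.append(Genotype(alleles=alleles, phased=True))
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=positions[j],
                ref="A",
                alts=("T",),
                qual=50.0,
                filter=("PASS",),
                info={"AA": "A"},
                genotypes=gts,
            )
        )
    return VariantTable(list(samples), records, standard_header({chrom: chrom_length}))


# -- FST recovery substrate ---------------------------------------------------


def simulate_fst_window(
    n_diploid_per_pop: int,
    n_sites: int,
    fst: float,
    seed: int,
    chrom: str = "chr1",
) -> tuple[VariantTable, PopulationModel]:
    """One window of unlinked biallelic sites under the two-population
    Balding–Nichols island model with expected FST = ``fst``."""
    spec = SimulationSpec(
        seed=seed,
        chrom_lengths={chrom: 10 * n_sites + 100},
        populations={"P1": n_diploid_per_pop, "P2": n_diploid_per_pop},
        freq_model="island",
        fst=fst,
    )
    rng = np.random.Generator(np.random.PCG64(seed))
    records = []
    for j in range(n_sites):
        freqs = _pop_frequencies(rng, spec)
        gts = _draw_genotypes(rng, spec, freqs)
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=1 + 10 * j,
                ref="A",
                alts=("T",),
                qual=50.0,
                filter=("PASS",),
                info={"AA": "A"},
                genotypes=gts,
            )
        )
    model = create_model(
        "island",
        {p: [f"{p}_{k + 1}" for k in range(n_diploid_per_pop)] for p in spec.populations},
        tree="(P1,P2)",
    )
    table = VariantTable(model.individuals(), records, standard_header(spec.chrom_lengths))
    return table, model
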