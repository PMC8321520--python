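# popgencore

A library and command-line toolkit for preparing population-genomic
analyses from multi-sample VCF files. It covers the stretch of a study that
lies between "I have a filtered VCF" and "I can run an inference program":
assigning individuals to populations with a reusable JSON model file,
site- and locus-level filtering, windowed summary statistics, extraction of
recombination-free haplotype blocks, BED interval algebra, per-haplotype
sequence reconstruction, multi-dimensional site frequency spectra, and
export to the input formats of IMa3, G-PhoCS, dadi, treemix, fastsimcoal2,
EIGENSTRAT and PLINK PED.

The intended user is a population geneticist assembling a multi-locus
demographic analysis — for example an isolation-with-migration (IM) study
of two closely related populations — who needs every preparation step to be
scriptable, reproducible from a seed, and consistent about which samples
belong to which population.

## The statistics at the core

**Tajima's D.** For a window with `n` haploid samples, `S` biallelic
segregating sites and mean pairwise diversity `π`,

    D = (π − S/a1) / sqrt(e1·S + e2·S·(S−1)),   a1 = Σ_{i<n} 1/i,

with the standard normalising constants a1, a2, b1, b2, c1, c2, e1, e2
evaluated at `n`. `π` is accumulated per site as `2p(1−p)·n_i/(n_i−1)` over
called alleles, which equals the mean number of pairwise differences when
no data are missing. `D` is flagged undefined (never silently zero) when
`S = 0` or the variance term vanishes.

**Weir–Cockerham FST.** Per biallelic site the among-population (a),
between-individual (b) and within-individual (c) variance components are
computed from per-population sample sizes, allele frequencies and observed
heterozygosities; the windowed estimate is the ratio of sums
`θ̂ = Σa / Σ(a+b+c)` over sites with defined components.

**Four-gamete test.** Two biallelic sites are incompatible with a single
non-recombining genealogy under infinite sites if all four gametes
(00, 01, 10, 11) occur among the haplotypes. `find_compatible_intervals`
returns every maximal run of pairwise-compatible sites of a phased locus,
and `extract_block` turns the chosen run into a new per-locus VCF — the
usual pre-filter before genealogy samplers that assume no intra-locus
recombination.

## Worked example

Everything below runs from a synthetic fixture set, so it is fully
reproducible without downloads:

```python
from popgencore import SimulationSpec, simulate_dataset, run_im_pipeline

data = simulate_dataset(SimulationSpec(seed=808))   # 7 diploids in 2 pops,
model = data.models["main"]                         # 100 candidate loci
result = run_im_pipeline(
    data.vcf, data.reference, data.loci, model,
    sample_n=20, sample_bins=2, seed=9, ima_out="loci.ima",
)
print(result.n_input_records, result.n_filtered_records,
      result.n_informative_loci, result.n_sampled_loci,
      result.n_surviving_loci)
```

prints

```
1049 1034 99 20 20
```

meaning: of 1049 input records, 1034 survive the site filters (biallelic,
no missing data, no indels, FILTER exactly PASS); 99 of the 100 candidate
loci carry at least 4 qualifying variants; 20 loci are drawn uniformly
across 2 bins of their Tajima's D values; and all 20 yield a four-gamete
compatible block with at least 2 variants. The resulting `loci.ima` begins

```
popgencore IM export
2
CT WC
(CT,WC)
20
```

— the population count, population names, population tree and the
locus-count line that IMa3 requires, followed by one fixed-width sequence
block per locus.

The same steps are available as CLI subcommands (`popgencore vcf-filter`,
`informative-loci-filter`, `vcf-calc`, `stat-sampler`, `vcf-split`,
`vcf-four-gamete`, `bed-utilities`, `vcf-to-ima`, ... — see
`popgencore --help`).

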