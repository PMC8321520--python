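# Methods

## Population models

A model is an ordered map population → individual IDs, optionally with a
newick-like population-tree string; a model file is an ordered list of
uniquely named models serialized as JSON
(`[{"name", "tree", "pops": {pop: {"inds": [...]}}}, ...]`). Population
order is the key order of the file and is preserved everywhere downstream
(statistics, SFS axes, exporter column order). An individual may appear in
several models of one file but never in two populations of the same model —
downstream exporters require disjoint populations, so the duplicate case is
an error rather than a warning. Unknown keys on a model object are carried
through read → write untouched, so files can hold extra metadata. The tree
string is only checked for balanced parentheses; full phylogeny validation
is out of scope. The IMa3 exporter requires a tree and refuses models
without one.

## VCF handling and coordinate conventions

Parsing goes through pysam (plain or bgzip VCF text); records live in a
plain in-memory table (samples, records, verbatim `##` header lines) and
are written back as VCF text, so read → write → read is the identity on the
canonical dialect, including genotype phase flags. Conventions, chosen
where the common toolkits agree and documented where they differ:

* BED is 0-based half-open, VCF POS 1-based: POS `p` is inside `(s, e]`
  iff `s < p ≤ e`.
* Allele classes (invariant / biallelic / multiallelic) are decided from
  the *called genotypes*, not the ALT column: a site where nobody carries
  the listed ALT is invariant. This makes the class consistent with the
  "exactly one distinct called allele" definition of invariance.
* MAF/MAC are computed over called alleles only; the multiallelic MAF is
  the least frequent called allele's frequency. MAF is therefore invariant
  under REF/ALT relabeling.
* "PASS required" is strict equality with `PASS`; a missing FILTER column
  fails the requirement.
* Sorting uses the `##contig` header order when present, else first
  appearance; ties are broken stably by input order.
* Locus (informativeness) filtering counts a record as a qualifying variant
  when it is polymorphic among called genotypes and not screened out by the
  ignore-indel / ignore-multiallelic / ignore-CpG switches. Missing data is
  counted per genotype by default; a `missing_per_site` switch counts
  affected sites instead, since either reading of "missing data count" is
  defensible.
* A site is "within a CpG" when the reference bases at (pos, pos+1) or
  (pos−1, pos) spell CG — the symmetric rule that covers both strands.
* Overlapping loci in splitting warn and duplicate records rather than
  erroring, to tolerate permissive BED inputs.
* Site-wise merging is keyed on (chrom, pos); a REF conflict at a shared
  key is an error, absent genotypes become missing, and a sample present in
  two inputs must make identical calls at shared sites.

## Tajima's D

Constants a1, a2, b1, b2, c1, c2, e1, e2 follow the original 1989
definitions at `n` = the table's haploid sample size (ploidy × samples);
per-site diversity uses the unbiased `2p(1−p)·n_i/(n_i−1)` with `n_i` the
called alleles at that site, so sites with sporadic missingness still
contribute correctly. With complete data the summed per-site form equals
the mean pairwise difference exactly, which is what the test oracle
computes by brute force. Multiallelic sites are excluded from `S` and `π`.
`D` is undefined when `S = 0` or the variance term is ≤ 0; undefined values
propagate as an explicit flag and serialize as `nan` in the statistic
table (`CHROM  BIN_START  BIN_END  N_SITES  <STAT>`).

## Weir–Cockerham FST

Per-site components use per-population counts of fully called diploid
genotypes (`n_i`), alternate-allele frequencies and observed heterozygote
frequencies. Sites are skipped (not zero-filled) when any population has no
called genotype, when more than two alleles are called, or when `n̄ ≤ 1` or
`n_c ≤ 0` leaves no degrees of freedom; monomorphic sites produce exact
zeros and contribute nothing to the ratio of sums. The windowed estimate
`Σa / Σ(a+b+c)` is undefined when the denominator is zero. Because the
components are symmetric in the allele labels, the estimate is invariant
under REF/ALT swaps and population relabeling (both property-tested).

Windows anchor at each chromosome's first record by default (`anchor="one"`
switches to position 1); both behaviours are offered because window
anchoring is a genuine ambiguity in windowed scans.

## Locus subsampling

The uniform scheme bins defined values into `bins` equal-width, right-closed
bins over the observed [min, max] and draws `⌊n/bins⌋` per non-empty bin,
plus one extra for the first `n mod bins` non-empty bins. When a bin holds
fewer loci than its quota the whole bin is taken and the shortfall is
redistributed over bins with spare loci (with a warning) so the output size
is exactly `n`; the exact-allocation contract holds whenever every bin is
sufficiently populated. All randomness uses numpy's PCG64 generator — a
named, versioned algorithm — so samples are identical across platforms for
a given seed. The same applies to BED sampling and random block selection.

## Four-gamete blocks

The haplotype matrix keeps one 0/1 column per biallelic site (the two
*called* alleles mapped to 0/1 in index order); multiallelic sites are
dropped by default (strict mode errors), invariant sites always dropped,
and unphased heterozygotes are an error since the test is defined on
haplotypes. Missing alleles simply drop that haplotype's gamete from a
pair's gamete set (strict mode errors), so a fourth gamete visible only
through a missing entry does not disqualify a pair.

Maximal intervals are found with a sweep that maintains, for each right
endpoint j, the smallest left endpoint L(j) such that [L(j), j] is pairwise
compatible; L is non-decreasing, so the binding constraint is the largest
k < j incompatible with j, and an interval is emitted exactly when
extending right would advance L. Correctness is defined by exhaustive
enumeration of all O(m²) pairs, which the test suite and the acceptance
script run against 1,000 random matrices; the sweep is an optimization.
Every site is covered by at least one interval (a single site is trivially
compatible). The single-block default selection is longest-by-site-count
with leftmost tie-break; random selection requires an explicit seed.

## Sequence reconstruction and exporters

Per-haplotype sequences are the reference substring with each SNP position
overwritten by the carried allele; missing alleles become `N` so absent
data stays visible downstream, and loci containing indels are rejected by
default (a skip-with-warning mode exists) so alignments stay rectangular,
which the IM/G-PhoCS formats require. IMa3 sequence names are fixed-width:
10 characters, left-justified, non-alphanumerics mapped to `_`. IM locus
defaults are mutation model `I` (infinite sites — consistent with
four-gamete pre-filtering) and inheritance scalar 1.0 (autosomes), both
overridable. Genetic positions default to 0.0 (EIGENSTRAT `.snp`) and 0
(PED `.map`); no genetic-map interpolation is attempted. Per-locus mutation
rate annotations for calibrated IMa3 runs are not emitted in this version.

## Site frequency spectra

The k-dimensional SFS has shape `(n_i + 1, ...)` over the model's
populations in model order. The ancestral allele comes from INFO `AA` when
present; otherwise REF is treated as ancestral with a prominent warning and
folding is recommended. Sites are skipped (with per-reason counters:
missing, multiallelic, monomorphic, unpolarized) rather than projected —
hypergeometric projection to smaller sample sizes is a deliberate non-goal
of this version. Folding maps each cell to whichever of (d, n−d) carries
fewer total derived copies, with a lexicographic tie-break exactly at half,
so totals are conserved cell-for-cell. Monomorphic corner cells are
excluded by default and included by flag, since downstream conventions
differ. The fastsimcoal2 `.obs` writer covers 1- and 2-population spectra
(`d<pop>_<count>` labels, rows over the second population); higher
dimensions use the flattened text dump with a self-describing header.

## Synthetic fixtures

The generator emulates the statistical structure the tests need, not a
full coalescent process:

* Allele frequencies are either shared across populations or drawn per
  population from the Balding–Nichols beta model
  `Beta(p(1−F)/F, (1−p)(1−F)/F)` around a uniform ancestral frequency, so
  the expected Weir–Cockerham FST is the divergence parameter F. Genotypes
  are independent Bernoulli draws given the frequency — there is no
  linkage, selection, or mutation-model realism, so passing tests show
  estimator correctness under the island model, not robustness to real
  LD structure.
* Default study conditions: one 250 kb chromosome, two populations of 4
  and 3 diploids (a seven-individual, two-population sampling design
  typical of small IM studies), 100 candidate loci of 1 kb with a mean of
  10 SNPs each, island divergence F = 0.1, and planted specials: 5 indels,
  3 multiallelic, 4 missing-genotype, 3 non-PASS and 5 CpG-context records.
  FST recovery uses 2 × 20 diploids and 50 sites per window over 200
  replicate windows — sizes at which the run completes in seconds while
  the Monte Carlo error of the mean is well below the ±0.02 check.
* Variant positions sit on a 3 bp grid so planted CpG dinucleotides (and
  their deliberate absence elsewhere) never collide with neighbouring
  records; accidental CG contexts at non-planted variant positions are
  broken during generation, making the CpG truth list exact.
* Recombination-free blocks mutate a random perfect genealogy: each site's
  derived set is a clade of one random topology, so within-block pairs show
  at most three gametes by construction. The first site of each subsequent
  block partially overlaps (without nesting) the previous block's last
  clade, which exhibits all four gametes, so maximal compatible intervals
  equal the planted blocks exactly — no rejection sampling involved.
* Records that must be countable by the filter tests (clean, CpG, missing,
  non-PASS) are forced to segregate by flipping one haplotype if a draw
  came out monomorphic; the FST-recovery generator applies no such forcing
  since monomorphic sites contribute zeros to both sums of the estimator.

All generators are deterministic (byte-identical output) from their seed.

## Numerical and degenerate-input choices

Undefined statistics are explicit flags end-to-end, never silent zeros.
Oracle agreement tolerances in the tests are 1e-10 (Tajima's D) and 1e-12
(FST components); the implementations and oracles compute through different
routes (per-site frequencies vs. literal pairwise differences; numpy
reductions vs. scalar loops), so agreement at that level is informative.
Empty inputs error early: empty locus lists, models without populations,
zero tallied SFS sites, writers with no loci. The problem sizes used in the
test suite and acceptance script (1,000 four-gamete matrices, 100 oracle
windows, 200 FST windows, 200 interval-algebra cases, 500 SFS sites) are
the package's standing verification conditions; they run in a few seconds
total.

## Known limitations

No BCF or tabix support; no genotype-likelihood fields; no Rm
(minimum-recombination) estimation or LD statistics; no SFS projection; no
binary PLINK output; phasing itself is out of scope — the four-gamete and
reconstruction steps consume already-phased input. The Tajima constants use
the table-wide haploid sample size, which slightly misstates the variance
in windows with heavy, uneven missingness; sites missing in most samples
should be filtered first.
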