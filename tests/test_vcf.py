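import numpy as np
import pytest

from popgencore import (
    Genotype,
    GenomicInterval,
    LocusFilterSpec,
    SiteFilterSpec,
    VariantRecord,
    VariantTable,
    concat_vcfs,
    filter_loci,
    filter_sites,
    is_cpg_site,
    list_chromosomes,
    list_samples,
    merge_vcfs,
    read_vcf,
    sort_vcf,
    split_by_loci,
    write_vcf,
)
from popgencore.simulate import standard_header

HEADER = standard_header({"chr1": 100_000, "chr2": 100_000})


def rec(pos, ref="A", alts=("T",), gts=((0, 0), (0, 1), (1, 1)), chrom="chr1",
        filter=("PASS",), phased=True, id=None):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alts=tuple(alts), id=id, qual=50.0,
        filter=filter, info={},
        genotypes=[Genotype(tuple(g), phased) for g in gts],
    )


def table(records, samples=("s1", "s2", "s3")):
    return VariantTable(list(samples), records, list(HEADER))


class TestRecordSummaries:
    def test_allele_classes_follow_called_genotypes(self):
        assert rec(1, gts=((0, 0), (0, 1), (1, 1))).is_biallelic
        assert rec(2, alts=("T", "G"), gts=((0, 1), (1, 2), (0, 0))).is_multiallelic
        assert rec(3, gts=((0, 0), (0, 0), (0, 0))).is_invariant
        # ALT listed but nobody carries it: invariant by the called-allele rule
        assert rec(4, gts=((0, 0), (0, 0), (None, None))).is_invariant

    def test_maf_over_called_alleles_only(self):
        r = rec(1, gts=((0, 1), (None, None), (1, 1)))
        assert r.minor_allele_frequency() == pytest.approx(1 / 4)
        assert r.minor_allele_count() == 1

    def test_maf_invariant_under_ref_alt_swap(self):
        gts = ((0, 0), (0, 1), (1, 1))
        swapped = tuple(tuple(1 - a for a in g) for g in gts)
        assert rec(1, gts=gts).minor_allele_frequency() == rec(
            1, ref="T", alts=("A",), gts=swapped
        ).minor_allele_frequency()


class TestFilterSites:
    def test_triallelic_removed_when_biallelic_required(self):
        t = table([rec(100), rec(200, alts=("T", "G"), gts=((0, 1), (1, 2), (0, 0)))])
        out = filter_sites(t, SiteFilterSpec(include_classes=frozenset({"biallelic"})))
        assert [r.pos for r in out.records] == [100]

    def test_non_pass_removed_when_pass_required(self):
        t = table([rec(100), rec(200, filter=("LowQual",)), rec(300, filter=())])
        out = filter_sites(t, SiteFilterSpec(require_filter="PASS"))
        assert [r.pos for r in out.records] == [100]

    def test_planted_composition_filtered_exactly(self):
        """5 indels, 3 multiallelic, 4 missing, 8 clean -> exactly the 8 clean."""
        records = []
        pos = 100
        for _ in range(5):
            records.append(rec(pos, ref="AT", alts=("A",))); pos += 10
        for _ in range(3):
            records.append(rec(pos, alts=("T", "G"), gts=((0, 1), (1, 2), (0, 0)))); pos += 10
        for _ in range(4):
            records.append(rec(pos, gts=((None, None), (0, 1), (1, 1)))); pos += 10
        clean_pos = []
        for _ in range(8):
            records.append(rec(pos)); clean_pos.append(pos); pos += 10
        spec = SiteFilterSpec(
            include_classes=frozenset({"biallelic"}), max_missing_count=0, drop_indels=True
        )
        out = filter_sites(table(records), spec)
        assert [r.pos for r in out.records] == clean_pos

    def test_sample_subset_restricts_columns_and_frequencies(self):
        t = table([rec(100, gts=((0, 0), (0, 1), (1, 1)))])
        out = filter_sites(t, SiteFilterSpec(samples=["s1", "s2"], min_maf=0.3))
        # among s1,s2 the ALT frequency is 1/4 < 0.3 -> removed
        assert out.samples == ["s1", "s2"] and len(out) == 0
        with pytest.raises(KeyError):
            filter_sites(t, SiteFilterSpec(samples=["nope"]))

    def test_region_and_id_filters(self):
        t = table([rec(100, id="rs1"), rec(200, id="rs2"), rec(300)])
        keep = filter_sites(t, SiteFilterSpec(include_regions=[GenomicInterval("chr1", 150, 250)]))
        assert [r.pos for r in keep.records] == [200]
        drop = filter_sites(t, SiteFilterSpec(exclude_ids=frozenset({"rs2"})))
        assert [r.pos for r in drop.records] == [100, 300]

    def test_invalid_spec_bounds_rejected(self):
        with pytest.raises(ValueError):
            SiteFilterSpec(min_maf=0.7)
        with pytest.raises(ValueError):
            SiteFilterSpec(include_classes=frozenset({"biallelic"}),
                           exclude_classes=frozenset({"biallelic"}))

    def test_idempotent_and_subsequence_on_random_tables(self):
        rng = np.random.Generator(np.random.PCG64(11))
        for trial in range(30):
            records = []
            for i in range(40):
                gts = tuple(
                    tuple(int(a) if rng.random() > 0.1 else None for a in rng.integers(0, 2, 2))
                    for _ in range(3)
                )
                records.append(
                    rec(10 * (i + 1), gts=gts,
                        filter=("PASS",) if rng.random() < 0.8 else ("LowQual",))
                )
            t = table(records)
            spec = SiteFilterSpec(
                include_classes=frozenset({"biallelic"}),
                max_missing_count=int(rng.integers(0, 3)),
                min_maf=float(rng.uniform(0, 0.3)),
                require_filter="PASS" if rng.random() < 0.5 else None,
            )
            once = filter_sites(t, spec)
            twice = filter_sites(once, spec)
            assert twice.records == once.records
            it = iter(t.records)
            assert all(any(r == s for s in it) for r in once.records), "not a subsequence"


class TestFilterLoci:
    def test_threshold_of_four_variants(self):
        t = table([rec(p) for p in (110, 120, 130)])
        locus = GenomicInterval("chr1", 100, 200)
        assert filter_loci(t, [locus], LocusFilterSpec(min_variants=4)) == []
        assert filter_loci(t, [locus], LocusFilterSpec(min_variants=3)) == [locus]

    def test_empty_spec_is_identity(self):
        t = table([rec(110)])
        loci = [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 300, 400)]
        assert filter_loci(t, loci, LocusFilterSpec()) == loci

    def test_cpg_context_rule(self):
        #        123456
        seq = "ACGTCG"
        assert is_cpg_site(seq, 2)   # C of CG
        assert is_cpg_site(seq, 3)   # G of CG
        assert not is_cpg_site(seq, 4)
        assert is_cpg_site(seq, 5) and is_cpg_site(seq, 6)

    def test_cpg_variants_not_counted_when_ignored(self):
        ref = {"chr1": "A" * 100 + "ACGT" * 30}
        # positions 102,106,... are C of CG; 120,140 are A (non-CpG)
        cpg_pos = [102, 106]
        clean_pos = [121, 141, 161]
        t = table([rec(p, ref="C") for p in cpg_pos] + [rec(p) for p in clean_pos])
        locus = GenomicInterval("chr1", 100, 200)
        spec = LocusFilterSpec(min_variants=4, ignore_cpg=True)
        assert filter_loci(t, [locus], spec, ref=ref) == []
        assert filter_loci(t, [locus], LocusFilterSpec(min_variants=4)) == [locus]
        with pytest.raises(ValueError):
            filter_loci(t, [locus], spec, ref=None)

    def test_min_length_and_reference_bounds(self):
        t = table([rec(110)])
        short = GenomicInterval("chr1", 100, 150)
        assert filter_loci(t, [short], LocusFilterSpec(min_length=100)) == []
        with pytest.raises(ValueError):
            filter_loci(t, [GenomicInterval("chr1", 0, 999_999)],
                        LocusFilterSpec(), ref={"chr1": "A" * 1000})


class TestSplit:
    def test_disjoint_split_partitions_covered_records(self):
        t = table([rec(p) for p in (10, 20, 30, 40, 110, 120, 130, 210, 220, 230)])
        loci = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 100, 200),
                GenomicInterval("chr1", 200, 300)]
        parts = split_by_loci(t, loci)
        assert [len(p) for _, p in parts] == [4, 3, 3]
        seen = [r.pos for _, p in parts for r in p.records]
        assert sorted(seen) == [r.pos for r in t.records]

    def test_empty_locus_keeps_header(self):
        t = table([rec(10)])
        [(_, sub)] = split_by_loci(t, [GenomicInterval("chr1", 5000, 6000)])
        assert len(sub) == 0 and sub.header_meta == t.header_meta

    def test_empty_locus_list_rejected_and_overlap_warns(self):
        t = table([rec(10)])
        with pytest.raises(ValueError):
            split_by_loci(t, [])
        with pytest.warns(UserWarning):
            split_by_loci(t, [GenomicInterval("chr1", 0, 50), GenomicInterval("chr1", 25, 75)])


class TestUtilities:
    def test_concat_counts_and_sample_mismatch(self):
        a = table([rec(p) for p in (10, 20, 30, 40, 50)])
        b = table([rec(p) for p in (60, 70, 80)])
        assert len(concat_vcfs([a, b])) == 8
        with pytest.raises(ValueError):
            concat_vcfs([a, table([rec(10, gts=((0, 0),))], samples=("only",))])

    def test_sort_idempotent_and_contig_order(self):
        shuffled = table([rec(30, chrom="chr2"), rec(10), rec(20, chrom="chr2"), rec(5)])
        s = sort_vcf(shuffled)
        assert [(r.chrom, r.pos) for r in s.records] == [
            ("chr1", 5), ("chr1", 10), ("chr2", 20), ("chr2", 30)]
        assert sort_vcf(s).records == s.records

    def test_merge_against_union_oracle(self):
        """Two 1-sample tables, 4 shared + 2 private sites -> 6 x 2 with missing."""
        shared = [10, 20, 30, 40]
        a = table([rec(p, gts=((0, 1),)) for p in shared + [50]], samples=("sA",))
        b = table([rec(p, gts=((1, 1),)) for p in shared + [60]], samples=("sB",))
        merged = merge_vcfs([a, b])
        assert merged.samples == ["sA", "sB"]
        by_pos = {r.pos: r for r in merged.records}
        assert sorted(by_pos) == [10, 20, 30, 40, 50, 60]
        assert by_pos[50].genotypes[1].alleles == (None, None)
        assert by_pos[60].genotypes[0].alleles == (None, None)
        for p in shared:
            assert by_pos[p].genotypes[0].alleles == (0, 1)
            assert by_pos[p].genotypes[1].alleles == (1, 1)

    def test_merge_conflicting_ref_rejected(self):
        a = table([rec(10, ref="A", gts=((0, 1),))], samples=("sA",))
        b = table([rec(10, ref="G", alts=("C",), gts=((0, 1),))], samples=("sB",))
        with pytest.raises(ValueError):
            merge_vcfs([a, b])

    def test_listing(self):
        t = table([rec(10), rec(20, chrom="chr2")])
        assert list_chromosomes(t) == ["chr1", "chr2"]
        assert list_samples(t) == ["s1", "s2", "s3"]


class TestFileRoundTrip:
    def test_read_write_read_preserves_everything(self, dataset, tmp_path):
        path = tmp_path / "x.vcf"
        write_vcf(dataset.vcf, path)
        back = read_vcf(path)
        assert back.samples == dataset.vcf.samples
        assert back.records == dataset.vcf.records
        path2 = tmp_path / "y.vcf"
        write_vcf(back, path2)
        assert path.read_text() == path2.read_text()

    def test_phase_flags_survive(self, tmp_path):
        t = table([rec(10, gts=((0, 1), (0, 1), (1, 1)), phased=True),
                   rec(20, gts=((0, 0), (0, 0), (1, 1)), phased=False)])
        path = tmp_path / "p.vcf"
        write_vcf(t, path)
        back = read_vcf(path)
        assert back.records[0].genotypes[0].phased
        assert not back.records[1].genotypes[1].phased
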