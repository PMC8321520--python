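from itertools import combinations

import numpy as np
import pytest

from popgencore import (
    GenomicInterval,
    TajimaContext,
    WindowStat,
    fst_components,
    read_stat_file,
    sample_loci,
    simulate_fst_window,
    tajimas_d,
    wc_fst,
    windowed_scan,
    write_stat_file,
)
from popgencore.model_io import create_model
from popgencore.simulate import haplotypes_to_table, random_haplotype_matrix

# ---------------------------------------------------------------- oracles


def tajima_oracle(matrix):
    """Straight-from-formula D on a complete 0/1 haplotype matrix.

    pi is computed as the literal mean of pairwise Hamming distances, not
    via per-site frequencies, so it is an independent route.
    """
    n, m = matrix.shape
    seg = [j for j in range(m) if 0 < matrix[:, j].sum() < n]
    S = len(seg)
    if S == 0:
        return None
    pairs = list(combinations(range(n), 2))
    pi = sum(int((matrix[i] != matrix[j]).sum()) for i, j in pairs) / len(pairs)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return None
    return (pi - S / a1) / np.sqrt(var)


def wc_oracle(pop_genotypes):
    """Weir-Cockerham per-site a, b, c from diploid genotype lists.

    ``pop_genotypes``: list (one per population) of lists of (a1, a2)
    allele pairs with alleles coded 0/1; None entries are uncalled
    individuals and excluded.
    """
    r = len(pop_genotypes)
    n_i, p_i, h_i = [], [], []
    for pop in pop_genotypes:
        called = [g for g in pop if g is not None]
        if not called:
            return None
        n = len(called)
        alt = sum(g[0] + g[1] for g in called)
        het = sum(1 for g in called if g[0] != g[1])
        n_i.append(n)
        p_i.append(alt / (2 * n))
        h_i.append(het / n)
    n_bar = sum(n_i) / r
    if n_bar <= 1:
        return None
    n_tot = sum(n_i)
    n_c = (n_tot - sum(x**2 for x in n_i) / n_tot) / (r - 1)
    if n_c <= 0:
        return None
    p_bar = sum(n * p for n, p in zip(n_i, p_i)) / n_tot
    s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * n_bar)
    h_bar = sum(n * h for n, h in zip(n_i, h_i)) / n_tot
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return a, b, c


def hap_window(matrix, positions=None):
    n_hap = matrix.shape[0]
    samples = [f"s{i}" for i in range(n_hap // 2)]
    table = haplotypes_to_table(matrix, positions or [1 + 10 * j for j in range(matrix.shape[1])], samples)
    window = GenomicInterval("chr1", 0, max(r.pos for r in table.records) + 1)
    return table, window


# ---------------------------------------------------------------- Tajima's D


class TestTajimasD:
    def test_worked_case_four_haplotypes(self):
        """n=4, derived columns (0,1,1,1),(0,0,1,1),(0,0,0,1): S=3, pi=10/6."""
        matrix = np.array(
            [[0, 0, 0],
             [1, 0, 0],
             [1, 1, 0],
             [1, 1, 1]], dtype=np.int8)
        table, window = hap_window(matrix)
        ws = tajimas_d(table, window)
        assert ws.value == pytest.approx(0.16766, abs=5e-5)
        assert ws.value == pytest.approx(tajima_oracle(matrix), abs=1e-12)
        ctx = TajimaContext.from_counts(4, 3, 10 / 6)
        assert ctx.a1 == pytest.approx(11 / 6)
        assert ws.value == pytest.approx(ctx.d(), abs=1e-12)

    def test_no_segregating_sites_is_undefined(self):
        matrix = np.zeros((4, 3), dtype=np.int8)
        matrix[:, 1] = 1  # monomorphic-derived column is not segregating
        table, window = hap_window(matrix)
        assert tajimas_d(table, window).value is None

    def test_matches_oracle_on_random_windows(self):
        """100 random complete windows agree with the formula oracle to 1e-10."""
        rng = np.random.Generator(np.random.PCG64(7))
        for _ in range(100):
            n_hap = 2 * int(rng.integers(2, 7))
            matrix, _ = random_haplotype_matrix(n_hap, int(rng.integers(2, 30)),
                                               seed=int(rng.integers(2**31)))
            table, window = hap_window(matrix)
            assert tajimas_d(table, window).value == pytest.approx(
                tajima_oracle(matrix), abs=1e-10)

    def test_unknown_chromosome_rejected(self):
        matrix, _ = random_haplotype_matrix(4, 3, seed=1)
        table, _ = hap_window(matrix)
        with pytest.raises(KeyError):
            tajimas_d(table, GenomicInterval("chrX", 0, 100))


# ---------------------------------------------------------------- WC FST


def two_pop_model(n_per_pop):
    return create_model(
        "m", {"P1": [f"P1_{i+1}" for i in range(n_per_pop)],
              "P2": [f"P2_{i+1}" for i in range(n_per_pop)]})


class TestWcFst:
    def test_fixed_difference_gives_one(self):
        table, model = simulate_fst_window(2, 1, 0.1, seed=0)
        from popgencore.vcf import Genotype
        for rec in table.records:
            rec.genotypes = [Genotype((0, 0), True), Genotype((0, 0), True),
                             Genotype((1, 1), True), Genotype((1, 1), True)]
        ws, comps = wc_fst(table, model, GenomicInterval("chr1", 0, 1000))
        assert ws.value == 1.0
        assert comps[0].b == 0.0 and comps[0].c == 0.0

    def test_monomorphic_window_is_undefined(self):
        table, model = simulate_fst_window(3, 4, 0.1, seed=1)
        from popgencore.vcf import Genotype
        for rec in table.records:
            rec.genotypes = [Genotype((0, 0), True)] * 6
        ws, comps = wc_fst(table, model, GenomicInterval("chr1", 0, 1000))
        assert ws.value is None and comps == []

    def test_components_match_oracle(self):
        """Per-site a, b, c equal the formula oracle to 1e-12 on random tables."""
        rng = np.random.Generator(np.random.PCG64(13))
        checked = 0
        for _ in range(120):
            n = int(rng.integers(2, 8))
            table, model = simulate_fst_window(n, 1, float(rng.uniform(0.02, 0.5)),
                                               seed=int(rng.integers(2**31)))
            rec = table.records[0]
            pop_idx = {p: [table.sample_index(i) for i in inds]
                       for p, inds in model.pops.items()}
            comp = fst_components(rec, pop_idx)
            pops = [[tuple(g.alleles) if not g.is_missing else None
                     for g in (rec.genotypes[j] for j in idx)]
                    for idx in pop_idx.values()]
            expected = wc_oracle(pops)
            if comp is None:
                assert rec.n_distinct_called() > 2 or expected is None
                continue
            a, b, c = expected
            assert comp.a == pytest.approx(a, abs=1e-12)
            assert comp.b == pytest.approx(b, abs=1e-12)
            assert comp.c == pytest.approx(c, abs=1e-12)
            checked += 1
        assert checked >= 100

    def test_invariant_under_population_relabeling_and_allele_swap(self):
        table, model = simulate_fst_window(6, 30, 0.15, seed=21)
        window = GenomicInterval("chr1", 0, 1000)
        ws, _ = wc_fst(table, model, window)
        relabeled = create_model("swapped", {"P2": model.pops["P2"], "P1": model.pops["P1"]})
        ws2, _ = wc_fst(table, relabeled, window)
        assert ws2.value == pytest.approx(ws.value, abs=1e-12)
        from popgencore.vcf import Genotype, VariantRecord, VariantTable
        flipped = VariantTable(
            table.samples,
            [VariantRecord(chrom=r.chrom, pos=r.pos, ref="T", alts=("A",), qual=r.qual,
                           filter=r.filter, info={},
                           genotypes=[Genotype(tuple(1 - a for a in g.alleles), g.phased)
                                      for g in r.genotypes])
             for r in table.records],
            table.header_meta)
        ws3, _ = wc_fst(flipped, model, window)
        assert ws3.value == pytest.approx(ws.value, abs=1e-12)

    def test_single_population_rejected(self):
        table, _ = simulate_fst_window(2, 2, 0.1, seed=2)
        solo = create_model("solo", {"P1": ["P1_1", "P1_2"]})
        with pytest.raises(ValueError):
            wc_fst(table, solo, GenomicInterval("chr1", 0, 100))

    def test_island_model_recovery(self):
        """Mean windowed estimate over 200 replicates within 0.02 of target."""
        target = 0.1
        values = []
        for i in range(200):
            table, model = simulate_fst_window(20, 50, target, seed=5_000 + i)
            ws, _ = wc_fst(table, model, GenomicInterval("chr1", 0, 600))
            values.append(ws.value)
        assert np.mean(values) == pytest.approx(target, abs=0.02)


# ---------------------------------------------------------------- scan


class TestWindowedScan:
    def test_single_window_tiling(self):
        matrix, _ = random_haplotype_matrix(8, 20, seed=3)
        positions = [1 + 500 * j for j in range(20)]  # spans 9.5 kb
        table = haplotypes_to_table(matrix, positions, [f"s{i}" for i in range(4)],
                                    chrom_length=20_000)
        out = windowed_scan(table, None, "tajimasd", 10_000, 10_000)
        assert len(out) == 1 and out[0].n_sites == 20

    def test_overlapping_windows_cover_expected_positions(self):
        matrix, _ = random_haplotype_matrix(6, 10, seed=4)
        positions = [1 + 100 * j for j in range(10)]  # last record at 901
        table = haplotypes_to_table(matrix, positions, [f"s{i}" for i in range(3)],
                                    chrom_length=5_000)
        size, step = 400, 200
        out = windowed_scan(table, None, "tajimasd", size, step)
        first, last = 1, 901
        expected_n = (last - first) // step + 1
        assert len(out) == expected_n
        assert [ws.start for ws in out] == [first + k * step for k in range(expected_n)]
        assert all(ws.end - ws.start + 1 == size for ws in out)

    def test_fst_scan_equals_per_window_calls(self):
        table, model = simulate_fst_window(4, 40, 0.2, seed=9)
        out = windowed_scan(table, model, "windowed-fst", 100, 100)
        for ws in out:
            direct, _ = wc_fst(table, model, GenomicInterval(ws.chrom, ws.start - 1, ws.end))
            assert ws.value == pytest.approx(direct.value, abs=1e-15)

    def test_unknown_statistic_rejected(self):
        table, model = simulate_fst_window(2, 2, 0.1, seed=1)
        with pytest.raises(ValueError):
            windowed_scan(table, model, "pi", 100, 100)


# ---------------------------------------------------------------- sampling


def make_stats(values):
    return [WindowStat("chr1", 1 + i * 100, (i + 1) * 100, "TajimaD", v, 5)
            for i, v in enumerate(values)]


class TestSampleLoci:
    def test_uniform_allocation_exact_when_bins_populated(self):
        values = [float(v) for v in np.linspace(0, 1, 100)]
        stats = make_stats(values)
        out = sample_loci(stats, "uniform", n=20, bins=4, seed=3)
        assert len(out) == 20
        edges = np.linspace(0, 1, 5)
        counts = np.histogram([ws.value for ws in out], bins=edges)[0]
        assert list(counts) == [5, 5, 5, 5]

    def test_same_seed_same_sample(self):
        stats = make_stats(list(np.random.Generator(np.random.PCG64(0)).normal(size=60)))
        a = sample_loci(stats, "uniform", n=12, bins=3, seed=9)
        b = sample_loci(stats, "uniform", n=12, bins=3, seed=9)
        assert a == b

    def test_random_scheme_draws_exact_count(self):
        stats = make_stats(list(np.random.Generator(np.random.PCG64(1)).normal(size=400)))
        out = sample_loci(stats, "random", n=300, seed=4)
        assert len(out) == 300
        assert all(ws in stats for ws in out)  # sub-multiset

    def test_undefined_values_excluded_and_errors(self):
        stats = make_stats([0.1, None, 0.5, None])
        out = sample_loci(stats, "random", n=2, seed=0)
        assert all(ws.defined for ws in out)
        with pytest.raises(ValueError):
            sample_loci(stats, "random", n=3, seed=0)
        with pytest.raises(ValueError):
            sample_loci(make_stats([None, None]), "random", n=1, seed=0)

    def test_shortfall_redistributed_with_warning(self):
        values = [0.0] * 19 + [100.0]  # top bin holds a single locus
        with pytest.warns(UserWarning):
            out = sample_loci(make_stats(values), "uniform", n=10, bins=2, seed=0)
        assert len(out) == 10


class TestStatTable:
    def test_round_trip_with_undefined(self, tmp_path):
        stats = make_stats([0.25, None, -1.5])
        path = tmp_path / "stats.tsv"
        write_stat_file(stats, path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header == ["CHROM", "BIN_START", "BIN_END", "N_SITES", "TajimaD"]
        assert "nan" in path.read_text()
        assert read_stat_file(path) == stats
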