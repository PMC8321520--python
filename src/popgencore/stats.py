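"""Windowed population-genetic summary statistics and locus subsampling.

Implements Tajima's D and the Weir–Cockerham (1984) variance-components
FST estimator over genomic windows, a sliding-window scanner, a
tab-separated statistic-table format, and seeded subsampling of loci either
at random or uniformly across equal-width bins of a statistic.

Tajima's D
----------
``D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1))`` with the constants
a1, a2, b1, b2, c1, c2, e1, e2 of Tajima (1989) evaluated at the haploid
sample size ``n``.  ``pi`` is the unbiased per-site heterozygosity
``2 p (1-p) n_i/(n_i - 1)`` summed over segregating sites, with ``n_i`` the
called haploid alleles at each site, which equals the mean number of
pairwise differences when no data are missing.  ``S`` counts biallelic
segregating sites.  D is undefined (flagged, never silently zero) when
``S = 0`` or the variance term is non-positive.

Weir–Cockerham FST
------------------
Per biallelic site the among-population (a), among-individual (b) and
within-individual (c) variance components are computed from per-population
sample sizes ``n_i`` (called diploid individuals), alternate-allele
frequencies ``p_i`` and observed heterozygote frequencies ``h_i``.  The
windowed estimate is the ratio of sums ``sum(a) / sum(a+b+c)`` over sites
with defined components.  Multiallelic sites are excluded from both
statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .bed import GenomicInterval
from .model_io import PopulationModel
from .vcf import VariantRecord, VariantTable

__all__ = [
    "WindowStat",
    "TajimaContext",
    "FstComponents",
    "tajimas_d",
    "wc_fst",
    "fst_components",
    "windowed_scan",
    "sample_loci",
    "stats_to_dataframe",
    "write_stat_file",
    "read_stat_file",
]


@dataclass(frozen=True)
class WindowStat:
    """One statistic value over one window (1-based inclusive bp)."""

    chrom: str
    start: int
    end: int
    stat: str
    value: float | None  # None = undefined, written as "nan"
    n_sites: int

    @property
    def defined(self) -> bool:
        return self.value is not None

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start - 1, self.end)


# -- Tajima's D ---------------------------------------------------------------


@dataclass(frozen=True)
class TajimaContext:
    """Sample size, segregating sites, pairwise diversity, and the Tajima
    (1989) normalising constants."""

    n: int
    S: int
    pi: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def from_counts(cls, n: int, S: int, pi: float) -> "TajimaContext":
        if n < 2:
            raise ValueError("Tajima's D requires n >= 2 haploid samples")
        a1 = sum(1.0 / i for i in range(1, n))
        a2 = sum(1.0 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(n=n, S=S, pi=pi, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)

    def d(self) -> float | None:
        if self.S == 0:
            return None
        var = self.e1 * self.S + self.e2 * self.S * (self.S - 1)
        if var <= 0:
            return None
        theta_w = self.S / self.a1
        return (self.pi - theta_w) / math.sqrt(var)


def _site_pi(rec: VariantRecord) -> float | None:
    """Unbiased per-site heterozygosity over called alleles; None if < 2 called."""
    counts = rec.called_allele_counts()
    n = sum(counts.values())
    if n < 2 or len(counts) != 2:
        return None
    p = next(iter(counts.values())) / n
    return 2.0 * p * (1.0 - p) * n / (n - 1.0)


def tajimas_d(table: VariantTable, window: GenomicInterval) -> WindowStat:
    """Tajima's D over the biallelic segregating sites in ``window``."""
    if window.chrom not in table.chromosomes():
        raise KeyError(f"chromosome {window.chrom!r} has no records in the table")
    recs = table.records_in(window)
    ploidy = max((len(g.alleles) for r in recs for g in r.genotypes), default=2)
    n = ploidy * len(table.samples)
    S = 0
    pi = 0.0
    for rec in recs:
        if rec.is_multiallelic:
            continue
        site = _site_pi(rec)
        if site is None:
            continue
        S += 1
        pi += site
    value = TajimaContext.from_counts(n, S, pi).d() if n >= 2 else None
    return WindowStat(window.chrom, window.start + 1, window.end, "TajimaD", value, len(recs))


# -- Weir-Cockerham FST -------------------------------------------------------


@dataclass(frozen=True)
class FstComponents:
    """Per-site variance components of the Weir–Cockerham estimator."""

    a: float
    b: float
    c: float
    p_bar: float
    n_bar: float
    n_c: float
    h_bar: float
    r: int

    @property
    def denominator(self) -> float:
        return self.a + self.b + self.c


def fst_components(
    rec: VariantRecord, pop_sample_idx: dict[str, list[int]]
) -> FstComponents | None:
    """Variance components at one site, or None when they are undefined.

    ``pop_sample_idx`` maps population name to genotype-column indices.
    Undefined when the site is not biallelic among called genotypes, when a
    population has no fully called genotype, or when the mean sample size
    leaves no degrees of freedom (n_bar <= 1 or n_c = 0).  Monomorphic sites
    yield a = b = c = 0.
    """
    if rec.n_distinct_called() > 2:
        return None
    alleles = sorted(rec.called_allele_counts())
    if not alleles:
        return None
    alt_allele = alleles[-1]  # frequency of the "second" allele; symmetric choice
    r = len(pop_sample_idx)
    n_i, p_i, h_i = [], [], []
    for idx in pop_sample_idx.values():
        n = 0
        alt = 0
        het = 0
        for j in idx:
            gt = rec.genotypes[j]
            if gt.is_missing:
                continue
            n += 1
            alt += sum(1 for a in gt.alleles if a == alt_allele)
            if gt.is_het:
                het += 1
        if n == 0:
            return None
        n_i.append(n)
        p_i.append(alt / (2.0 * n))
        h_i.append(het / n)
    n_i_arr = np.asarray(n_i, dtype=float)
    p_arr = np.asarray(p_i)
    h_arr = np.asarray(h_i)
    n_bar = n_i_arr.mean()
    n_total = n_i_arr.sum()
    if n_bar <= 1.0:
        return None
    n_c = (n_total - (n_i_arr**2).sum() / n_total) / (r - 1.0)
    if n_c <= 0:
        return None
    p_bar = (n_i_arr * p_arr).sum() / n_total
    s2 = (n_i_arr * (p_arr - p_bar) ** 2).sum() / ((r - 1.0) * n_bar)
    h_bar = (n_i_arr * h_arr).sum() / n_total

    a = (n_bar / n_c) * (
        s2 - (1.0 / (n_bar - 1.0)) * (p_bar * (1 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1 - p_bar) - s2 * (r - 1.0) / r - h_bar * (2 * n_bar - 1) / (4.0 * n_bar)
    )
    c = h_bar / 2.0
    return FstComponents(a=a, b=b, c=c, p_bar=p_bar, n_bar=n_bar, n_c=n_c, h_bar=h_bar, r=r)


def wc_fst(
    table: VariantTable, model: PopulationModel, window: GenomicInterval
) -> tuple[WindowStat, list[FstComponents]]:
    """Windowed Weir–Cockerham FST = sum(a)/sum(a+b+c) over defined sites.

    Returns the window statistic together with the per-site components of
    every site that contributed (monomorphic sites contribute zeros and are
    omitted from the component list).
    """
    if model.n_pops < 2:
        raise ValueError("FST requires at least two populations")
    pop_idx = {
        pop: [table.sample_index(ind) for ind in inds] for pop, inds in model.pops.items()
    }
    num = 0.0
    den = 0.0
    comps = []
    n_sites = 0
    for rec in table.records_in(window):
        comp = fst_components(rec, pop_idx)
        if comp is None:
            continue
        if comp.denominator == 0.0 and comp.a == 0.0:
            continue  # monomorphic: contributes nothing
        n_sites += 1
        comps.append(comp)
        num += comp.a
        den += comp.denominator
    value = num / den if den != 0.0 else None
    stat = WindowStat(window.chrom, window.start + 1, window.end, "Fst", value, n_sites)
    return stat, comps


# -- windowed scan ------------------------------------------------------------


def windowed_scan(
    table: VariantTable,
    model: PopulationModel | None,
    stat: Literal["tajimasd", "windowed-fst"],
    window_size: int,
    step: int,
    anchor: Literal["first-record", "one"] = "first-record",
    emit_empty: bool = True,
) -> list[WindowStat]:
    """Tile each chromosome with windows and evaluate one statistic per window.

    Windows start at the chromosome's first record by default (``anchor=
    "one"`` starts at position 1) and advance by ``step`` until the last
    record is covered.  Windows with no data carry the undefined flag and can
    be suppressed with ``emit_empty=False``.
    """
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be >= 1")
    if stat not in ("tajimasd", "windowed-fst"):
        raise ValueError(f"unknown statistic {stat!r}")
    if stat == "windowed-fst" and model is None:
        raise ValueError("windowed-fst requires a population model")
    out: list[WindowStat] = []
    for chrom in table.chromosomes():
        positions = [r.pos for r in table.records if r.chrom == chrom]
        first, last = min(positions), max(positions)
        start = first if anchor == "first-record" else 1
        while start <= last:
            win = GenomicInterval(chrom, start - 1, start + window_size - 1)
            if stat == "tajimasd":
                ws = tajimas_d(table, win)
            else:
                ws, _ = wc_fst(table, model, win)
            if ws.n_sites or emit_empty:
                out.append(ws)
            start += step
    return out


# -- locus subsampling --------------------------------------------------------


def sample_loci(
    stats: Sequence[WindowStat],
    scheme: Literal["uniform", "random"],
    n: int,
    bins: int = 1,
    seed: int = 0,
) -> list[WindowStat]:
    """Subsample loci by their statistic value, reproducibly from ``seed``.

    ``random`` draws a simple random sample without replacement from the
    defined-value loci.  ``uniform`` splits the observed [min, max] value
    range into ``bins`` equal-width right-closed bins and draws
    ``n // bins`` loci per non-empty bin, plus one extra for the first
    ``n % bins`` non-empty bins.  If a bin holds fewer loci than its quota,
    the whole bin is taken and the shortfall is redistributed over the
    remaining bins (with a warning), keeping the output size exactly ``n``.

    Randomness comes from numpy's PCG64 generator, so samples are identical
    across platforms for a given seed.
    """
    defined = [ws for ws in stats if ws.defined]
    if not defined:
        raise ValueError("all statistic values are undefined")
    if n > len(defined):
        raise ValueError(f"cannot sample {n} of {len(defined)} defined loci")
    rng = np.random.Generator(np.random.PCG64(seed))
    if scheme == "random":
        idx = sorted(rng.choice(len(defined), size=n, replace=False))
        return [defined[i] for i in idx]
    if scheme != "uniform":
        raise ValueError(f"unknown sampling scheme {scheme!r}")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    values = np.asarray([ws.value for ws in defined])
    lo, hi = values.min(), values.max()
    if hi == lo:
        edges = np.linspace(lo - 0.5, hi + 0.5, bins + 1)
    else:
        edges = np.linspace(lo, hi, bins + 1)
    # right-closed bins; lowest bin also closed on the left
    bin_of = np.clip(np.searchsorted(edges, values, side="left") - 1, 0, bins - 1)
    members = [np.flatnonzero(bin_of == b) for b in range(bins)]
    nonempty = [b for b in range(bins) if len(members[b])]
    quota = {b: n // bins for b in nonempty}
    for b in nonempty[: n % bins]:
        quota[b] += 1
    shortfall = n - sum(min(quota[b], len(members[b])) for b in nonempty)
    if shortfall:
        warnings.warn(
            f"{shortfall} draws redistributed across bins with spare loci"
        )
        spare = {b: len(members[b]) - quota[b] for b in nonempty}
        while shortfall > 0:
            for b in nonempty:
                if shortfall == 0:
                    break
                if spare[b] > 0:
                    quota[b] += 1
                    spare[b] -= 1
                    shortfall -= 1
    chosen: list[int] = []
    for b in nonempty:
        take = min(quota[b], len(members[b]))
        chosen.extend(rng.choice(members[b], size=take, replace=False))
    return [defined[i] for i in sorted(chosen)]


# -- statistic-table I/O ------------------------------------------------------


def stats_to_dataframe(stats: Sequence[WindowStat]) -> pd.DataFrame:
    if not stats:
        raise ValueError("no window statistics to tabulate")
    name = stats[0].stat
    return pd.DataFrame(
        {
            "CHROM": [ws.chrom for ws in stats],
            "BIN_START": [ws.start for ws in stats],
            "BIN_END": [ws.end for ws in stats],
            "N_SITES": [ws.n_sites for ws in stats],
            name: [ws.value if ws.defined else float("nan") for ws in stats],
        }
    )


def write_stat_file(stats: Sequence[WindowStat], path) -> None:
    """Tab-separated statistic table: CHROM, BIN_START, BIN_END, N_SITES, <STAT>."""
    stats_to_dataframe(stats).to_csv(path, sep="\t", index=False, na_rep="nan")


def read_stat_file(path) -> list[WindowStat]:
    df = pd.read_csv(path, sep="\t")
    stat_name = df.columns[-1]
    out = []
    for row in df.itertuples(index=False):
        value = getattr(row, stat_name) if stat_name.isidentifier() else row[-1]
        out.append(
            WindowStat(
                chrom=str(row.CHROM),
                start=int(row.BIN_START),
                end=int(row.BIN_END),
                stat=stat_name,
                value=None if pd.isna(value) else float(value),
                n_sites=int(row.N_SITES),
            )
        )
    return out
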