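"""Multi-dimensional site frequency spectrum (SFS) construction.

For a model with k populations of haploid sizes n_1..n_k, the SFS is a
k-dimensional integer array of shape (n_1+1, ..., n_k+1); each biallelic
site with derived-allele counts (d_1, ..., d_k) increments exactly one
cell.  Sites with a missing genotype among the model individuals, and
non-biallelic sites, are skipped and counted.  The ancestral allele is
taken from the INFO ``AA`` key when present; otherwise REF is treated as
ancestral (with a warning — folding is recommended when polarization is
unknown).

Output dialects: a fastsimcoal2-style observed-SFS text file (".obs": a
first line ``1 observations`` then a dimension-labelled count matrix, 1- or
2-population) and a plain flattened dump with a header giving dimensions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model_io import PopulationModel
from .vcf import VariantTable

__all__ = ["SfsArray", "build_sfs", "fold_sfs", "write_fsc_obs", "write_sfs_flat", "read_sfs_flat"]


@dataclass
class SfsArray:
    """k-dimensional allele-count histogram over the model's populations."""

    counts: np.ndarray  # integer counts, shape = (n_i + 1 per population)
    pop_names: list[str]
    haploid_sizes: list[int]
    polarization: str = "derived"  # "derived" | "folded"
    skipped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        expected = tuple(n + 1 for n in self.haploid_sizes)
        if self.counts.shape != expected:
            raise ValueError(f"SFS shape {self.counts.shape} != expected {expected}")
        if (self.counts < 0).any():
            raise ValueError("negative SFS cell count")

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())


def _ancestral_index(rec, warn_state: dict) -> int:
    aa = rec.info.get("AA")
    if aa is not None and aa is not True:
        aa = str(aa).upper()
        for i, allele in enumerate(rec.alleles):
            if allele.upper() == aa:
                return i
        return -1  # AA names an allele not at this site
    if not warn_state.get("warned"):
        warnings.warn(
            "no INFO/AA ancestral allele: treating REF as ancestral "
            "(consider folding the spectrum)"
        )
        warn_state["warned"] = True
    return 0


def build_sfs(
    vcf: VariantTable,
    model: PopulationModel,
    polarization: str = "derived",
    include_monomorphic: bool = False,
) -> SfsArray:
    """Tally one SFS cell per usable site; skip counters are recorded.

    A site is usable when, among the model individuals, every genotype is
    called and exactly two distinct alleles segregate (monomorphic sites
    land in the all-ancestral/all-derived corner cells and are excluded
    unless ``include_monomorphic``).  ``polarization="folded"`` folds the
    derived spectrum before returning it.
    """
    if polarization not in ("derived", "folded"):
        raise ValueError(f"unknown polarization {polarization!r}")
    inds = model.individuals()
    sub = vcf.subset_samples(inds)  # raises on absent individuals
    pop_cols = {}
    offset = 0
    for pop, members in model.pops.items():
        pop_cols[pop] = list(range(offset, offset + len(members)))
        offset += len(members)
    ploidy = max((len(g.alleles) for r in sub.records for g in r.genotypes), default=2)
    sizes = [ploidy * len(m) for m in model.pops.values()]
    counts = np.zeros(tuple(n + 1 for n in sizes), dtype=np.int64)
    skipped = {"missing": 0, "multiallelic": 0, "monomorphic": 0, "unpolarized": 0}
    warn_state: dict = {}
    for rec in sub.records:
        if any(g.is_missing for g in rec.genotypes):
            skipped["missing"] += 1
            continue
        distinct = rec.called_allele_counts()
        if len(distinct) > 2:
            skipped["multiallelic"] += 1
            continue
        anc = _ancestral_index(rec, warn_state)
        if anc < 0 or (len(distinct) == 2 and anc not in distinct):
            skipped["unpolarized"] += 1
            continue
        if len(distinct) == 1:
            if not include_monomorphic:
                skipped["monomorphic"] += 1
                continue
            cell = tuple(
                0 if next(iter(distinct)) == anc else n for n in sizes
            )
        else:
            cell = tuple(
                sum(
                    1
                    for j in cols
                    for a in rec.genotypes[j].alleles
                    if a != anc
                )
                for cols in pop_cols.values()
            )
        counts[cell] += 1
    sfs = SfsArray(
        counts=counts,
        pop_names=model.pop_names,
        haploid_sizes=sizes,
        polarization="derived",
        skipped=skipped,
    )
    if sfs.n_sites == 0:
        raise ValueError("zero tallied sites")
    return fold_sfs(sfs) if polarization == "folded" else sfs


def fold_sfs(s: SfsArray) -> SfsArray:
    """Merge each cell with its ancestral/derived mirror (minor-allele fold).

    A cell d is mapped to its complement (n - d) when the complement carries
    fewer total derived copies (lexicographic tie-break at exactly half), so
    every site count lands on one canonical cell and the total is preserved.
    """
    if s.polarization == "folded":
        raise ValueError("spectrum is already folded")
    folded = np.zeros_like(s.counts)
    n = np.asarray(s.haploid_sizes)
    half = n.sum() / 2.0
    for cell in itertools.product(*(range(k + 1) for k in n)):
        comp = tuple(int(x) for x in (n - np.asarray(cell)))
        total = sum(cell)
        if total < half or (total == half and cell <= comp):
            keep = cell
        else:
            keep = comp
        folded[keep] += s.counts[cell]
    return SfsArray(
        counts=folded,
        pop_names=list(s.pop_names),
        haploid_sizes=list(s.haploid_sizes),
        polarization="folded",
        skipped=dict(s.skipped),
    )


def write_fsc_obs(s: SfsArray, path) -> None:
    """fastsimcoal2 observed-SFS text for 1 or 2 populations.

    Cell labels follow the d<pop>_<count> convention (``m`` instead of
    ``d`` for folded spectra).
    """
    tag = "d" if s.polarization == "derived" else "m"
    k = len(s.haploid_sizes)
    lines = ["1 observations"]
    if k == 1:
        n0 = s.haploid_sizes[0]
        lines.append("\t".join(f"{tag}0_{i}" for i in range(n0 + 1)))
        lines.append("\t".join(str(int(c)) for c in s.counts))
    elif k == 2:
        n0, n1 = s.haploid_sizes
        lines.append("\t" + "\t".join(f"{tag}0_{j}" for j in range(n0 + 1)))
        # rows iterate the second population, columns the first (jointDAFpop1_0 layout)
        for i in range(n1 + 1):
            row = [f"{tag}1_{i}"] + [str(int(s.counts[j, i])) for j in range(n0 + 1)]
            lines.append("\t".join(row))
    else:
        raise ValueError("the .obs dialect covers 1 or 2 populations; use write_sfs_flat")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_sfs_flat(s: SfsArray, path) -> None:
    """Flattened dump: a header with dimensions/populations, then C-order counts."""
    with open(path, "w") as fh:
        fh.write(
            "# dims=%s pops=%s polarization=%s\n"
            % (
                ",".join(str(n + 1) for n in s.haploid_sizes),
                ",".join(s.pop_names),
                s.polarization,
            )
        )
        fh.write(" ".join(str(int(c)) for c in s.counts.ravel(order="C")) + "\n")


def read_sfs_flat(path) -> SfsArray:
    with open(path) as fh:
        header = fh.readline().strip()
        values = [int(x) for x in fh.readline().split()]
    meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
    dims = [int(d) for d in meta["dims"].split(",")]
    return SfsArray(
        counts=np.array(values, dtype=np.int64).reshape(dims),
        pop_names=meta["pops"].split(","),
        haploid_sizes=[d - 1 for d in dims],
        polarization=meta["polarization"],
    )
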