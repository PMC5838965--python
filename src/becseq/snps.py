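"""GWAS-integration utilities on generic SNP association tables.

Implements the restriction/intersection/validation procedure used to carry
a candidate-gene expression finding into GWAS summary statistics: restrict
an association table to putative cis-regulatory regions, intersect with the
targeted genes (with a configurable flank), keep nominally significant
SNPs, Bonferroni-validate lead SNPs queried in an independent cohort, and
compute D' linkage from two-site haplotype counts.

Coordinate conventions: SNP positions are 1-based on input (VCF
convention); intervals are 0-based half-open (BED convention) internally
and in all BED I/O.  A SNP at 1-based position P overlaps interval
[start, end) iff start <= P-1 < end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpAssociation",
    "GenomicIntervalSet",
    "HaplotypeCounts",
    "restrict_to_regions",
    "intersect_genes",
    "filter_significant",
    "validate_bonferroni",
    "d_prime",
    "read_bed",
    "read_snp_table",
]


@dataclass(frozen=True)
class SnpAssociation:
    snp_id: str
    chromosome: str
    position: int          # 1-based
    p: float
    phenotype: str = ""    # e.g. CB or EM sub-phenotype tag
    effect_allele: str = ""
    genes: tuple[str, ...] = ()  # filled by intersect_genes

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"{self.snp_id}: position must be positive (1-based)")
        if not 0 < self.p <= 1:
            raise ValueError(f"{self.snp_id}: p must be in (0, 1]")


@dataclass
class GenomicIntervalSet:
    """Labeled 0-based half-open intervals, indexed for sorted-sweep lookup."""

    intervals: list[tuple[str, int, int, str]]  # (chrom, start, end, label)
    _by_chrom: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, start, end, label in self.intervals:
            if start >= end:
                raise ValueError(f"interval {label}: start {start} >= end {end}")
            by_chrom.setdefault(chrom, []).append((start, end, label))
        # sort by start; keep per-chromosome running max of ends so a
        # binary search on starts plus a short backward scan is sufficient
        self._by_chrom = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts = np.array([s for s, _, _ in ivs])
            self._by_chrom[chrom] = (starts, ivs)

    @property
    def chromosomes(self) -> set[str]:
        return set(self._by_chrom)

    def overlapping(self, chrom: str, pos0: int) -> list[str]:
        """Labels of intervals containing 0-based position ``pos0``."""
        if chrom not in self._by_chrom:
            return []
        starts, ivs = self._by_chrom[chrom]
        hi = int(np.searchsorted(starts, pos0, side="right"))
        labels = [lab for s, e, lab in ivs[:hi] if s <= pos0 < e]
        return labels

    def padded(self, flank: int) -> "GenomicIntervalSet":
        return GenomicIntervalSet(
            [(c, max(0, s - flank), e + flank, lab)
             for c, s, e, lab in self.intervals]
        )


@dataclass(frozen=True)
class HaplotypeCounts:
    """Counts of the four two-site haplotypes AB, Ab, aB, ab."""

    n_AB: int
    n_Ab: int
    n_aB: int
    n_ab: int

    def __post_init__(self) -> None:
        counts = (self.n_AB, self.n_Ab, self.n_aB, self.n_ab)
        if min(counts) < 0:
            raise ValueError("haplotype counts must be non-negative")
        if sum(counts) == 0:
            raise ValueError("no haplotypes observed")


def _check_chromosomes(
    snps: Sequence[SnpAssociation], regions: GenomicIntervalSet
) -> None:
    """Guard against naming-scheme mismatch ('chr1' vs '1')."""
    snp_chroms = {s.chromosome for s in snps}
    region_chroms = regions.chromosomes
    if not snp_chroms or not region_chroms:
        return

    def stripped(names: set[str]) -> set[str]:
        return {n.removeprefix("chr") for n in names}

    direct = snp_chroms & region_chroms
    if not direct and (stripped(snp_chroms) & stripped(region_chroms)):
        raise ValueError(
            "chromosome naming mismatch between SNP table and intervals: "
            f"SNPs use {sorted(snp_chroms)[:5]}, intervals use "
            f"{sorted(region_chroms)[:5]}"
        )


def restrict_to_regions(
    snps: Sequence[SnpAssociation], regions: GenomicIntervalSet
) -> list[SnpAssociation]:
    """Keep SNPs whose position falls inside any region."""
    _check_chromosomes(snps, regions)
    return [
        s for s in snps if regions.overlapping(s.chromosome, s.position - 1)
    ]


def intersect_genes(
    snps: Sequence[SnpAssociation],
    gene_intervals: GenomicIntervalSet,
    flank: int = 10_000,
) -> list[SnpAssociation]:
    """Keep SNPs within a gene span +/- ``flank`` bp; annotate gene labels.

    A SNP overlapping several (padded) gene spans carries every label.
    """
    _check_chromosomes(snps, gene_intervals)
    padded = gene_intervals.padded(flank)
    out = []
    for s in snps:
        labels = padded.overlapping(s.chromosome, s.position - 1)
        if labels:
            out.append(replace(s, genes=tuple(sorted(set(labels)))))
    return out


def per_gene_counts(snps: Iterable[SnpAssociation]) -> pd.Series:
    counts: dict[str, int] = {}
    for s in snps:
        for g in s.genes:
            counts[g] = counts.get(g, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def filter_significant(
    snps: Sequence[SnpAssociation], alpha: float = 0.05
) -> list[SnpAssociation]:
    """Strict nominal filter p < alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return [s for s in snps if s.p < alpha]


def validate_bonferroni(
    p_values: dict[str, float], alpha: float = 0.05, m: int | None = None
) -> tuple[dict[str, bool], float]:
    """Bonferroni validation of follow-up queries.

    ``m`` defaults to the number of queries (e.g. one SNP tested in two
    sub-phenotypes gives m = 2 and threshold alpha/2).
    """
    if m is None:
        m = len(p_values)
    if m < 1:
        raise ValueError("m must be >= 1")
    threshold = alpha / m
    return {k: p < threshold for k, p in p_values.items()}, threshold


def d_prime(counts: HaplotypeCounts) -> float:
    """Normalized linkage disequilibrium D' from two-site haplotype counts.

    D = p_AB - p_A p_B; D' = |D| / D_max where D_max = min(p_A p_b, p_a p_B)
    for D > 0 and min(p_A p_B, p_a p_b) for D < 0.  D' = 1 means at most
    three of the four haplotypes are observed (complete linkage).
    """
    n = counts.n_AB + counts.n_Ab + counts.n_aB + counts.n_ab
    p_ab_hap = counts.n_AB / n
    p_a = (counts.n_AB + counts.n_Ab) / n  # freq of allele A at site 1
    p_b = (counts.n_AB + counts.n_aB) / n  # freq of allele B at site 2
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("monomorphic site: D' undefined")
    d = p_ab_hap - p_a * p_b
    if d == 0:
        return 0.0
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    return float(abs(d) / d_max)


# ---------------------------------------------------------------------------
# I/O


def read_bed(path) -> GenomicIntervalSet:
    """Read a 3+ column BED (chrom, start, end[, name]) as an interval set."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"],
        usecols=[0, 1, 2, 3] if _bed_has_names(path) else [0, 1, 2],
    )
    if "name" not in df.columns:
        df["name"] = [f"region{i}" for i in range(len(df))]
    return GenomicIntervalSet(
        [(str(r.chrom), int(r.start), int(r.end), str(r.name))
         for r in df.itertuples(index=False)]
    )


def _bed_has_names(path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return len(line.rstrip("\n").split("\t")) >= 4
    return False


def read_snp_table(path) -> list[SnpAssociation]:
    """Read a SNP association TSV (snp_id, chrom, pos, p[, phenotype])."""
    df = pd.read_csv(path, sep="\t")
    need = {"snp_id", "chrom", "pos", "p"}
    if not need <= set(df.columns):
        raise ValueError(f"SNP table missing columns {sorted(need - set(df.columns))}")
    return [
        SnpAssociation(
            str(r.snp_id), str(r.chrom), int(r.pos), float(r.p),
            phenotype=str(getattr(r, "phenotype", "")),
        )
        for r in df.itertuples(index=False)
    ]
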