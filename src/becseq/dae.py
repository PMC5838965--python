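"""Differential allelic expression (DAE) by cDNA-vs-gDNA variance comparison.

In a heterozygote, genomic DNA carries exactly one copy of each allele, so
the gDNA allelic read ratio is centred on 1 and its spread across subjects
reflects analytic noise only.  If a linked cis-regulatory variant alters
transcription of one gene copy, the cDNA allelic ratio of heterozygous
subjects is pushed away from 1 — in a direction set by the (unobserved)
phase — so inter-individual variance of the log2 cDNA ratio exceeds the
gDNA variance.  The test statistic is the variance ratio

    F = var(log2 cDNA ratios) / var(log2 gDNA ratios)

referred to the F distribution with (n_cdna - 1, n_gdna - 1) degrees of
freedom.  The upper tail is the default alternative (excess cDNA variance
is the signal of cis-regulation); a two-sided option is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AlleleCountRecord",
    "GenotypeCall",
    "DAEResult",
    "call_genotype",
    "log2_ratio",
    "dae_f_test",
    "hwe_test",
    "adjust_bonferroni",
    "run_dae",
]


@dataclass(frozen=True)
class AlleleCountRecord:
    subject_id: str
    site_id: str
    material: str  # {cDNA, gDNA}
    count_A: int
    count_B: int

    def __post_init__(self) -> None:
        if self.count_A < 0 or self.count_B < 0:
            raise ValueError("allele counts must be non-negative")
        if self.material not in ("cDNA", "gDNA"):
            raise ValueError(f"bad material {self.material!r}")

    @property
    def total(self) -> int:
        return self.count_A + self.count_B

    @property
    def minor_fraction(self) -> float:
        if self.total == 0:
            return float("nan")
        return min(self.count_A, self.count_B) / self.total


@dataclass(frozen=True)
class GenotypeCall:
    subject_id: str
    site_id: str
    call: str  # {het, hom_A, hom_B, ambiguous}
    minor_fraction: float


@dataclass(frozen=True)
class DAEResult:
    site_id: str
    gene: str
    n_het_cdna: int
    n_het_gdna: int
    var_cdna: float
    var_gdna: float
    F: float
    p: float
    p_adjusted: float | None = None
    flag: str | None = None


def call_genotype(
    record: AlleleCountRecord,
    het_band: tuple[float, float] = (0.25, 0.75),
    hom_max: float = 0.05,
) -> GenotypeCall:
    """Call genotype from gDNA allele counts.

    A heterozygote has minor-allele read fraction inside ``het_band``; a
    homozygote at most ``hom_max``; anything between is ambiguous and is
    excluded from downstream analysis.
    """
    if record.material != "gDNA":
        raise ValueError("genotype calls are derived from gDNA records only")
    lo, hi = het_band
    if not 0 < lo < hi <= 1:
        raise ValueError("het_band must satisfy 0 < lo < hi <= 1")
    mf = record.minor_fraction
    if np.isnan(mf):
        call = "ambiguous"
    elif lo <= mf <= hi:
        call = "het"
    elif mf <= hom_max:
        call = "hom_A" if record.count_A >= record.count_B else "hom_B"
    else:
        call = "ambiguous"
    return GenotypeCall(record.subject_id, record.site_id, call, mf)


def log2_ratio(record: AlleleCountRecord) -> float:
    """log2(count_A / count_B) for a called heterozygote.

    A zero count in either allele makes the ratio undefined; callers should
    exclude such records (with a warning) rather than clamp them.
    """
    if record.count_A <= 0 or record.count_B <= 0:
        raise ValueError(
            f"{record.subject_id}/{record.site_id}: zero allele count, "
            "ratio undefined"
        )
    return float(np.log2(record.count_A / record.count_B))


def dae_f_test(
    cdna_ratios: np.ndarray,
    gdna_ratios: np.ndarray,
    site_id: str = "",
    gene: str = "",
    two_sided: bool = False,
) -> DAEResult:
    """Variance-ratio F test of cDNA vs gDNA log2 allelic ratios.

    Uses unbiased (n-1) sample variances.  Default alternative is one-sided
    upper tail (cDNA variance larger).
    """
    cdna = np.asarray(cdna_ratios, dtype=float)
    gdna = np.asarray(gdna_ratios, dtype=float)
    if cdna.size < 3 or gdna.size < 3:
        raise ValueError("need at least 3 ratios per group")
    var_c = float(np.var(cdna, ddof=1))
    var_g = float(np.var(gdna, ddof=1))
    flag = None
    if var_g == 0:
        return DAEResult(
            site_id, gene, cdna.size, gdna.size, var_c, var_g,
            float("inf"), np.finfo(float).tiny, flag="gdna_variance_zero",
        )
    F = var_c / var_g
    df1, df2 = cdna.size - 1, gdna.size - 1
    p_upper = float(stats.f.sf(F, df1, df2))
    if two_sided:
        p = float(min(1.0, 2 * min(p_upper, 1 - p_upper)))
    else:
        p = p_upper
    return DAEResult(site_id, gene, cdna.size, gdna.size, var_c, var_g, F, p, flag=flag)


def hwe_test(n_AA: int, n_AB: int, n_BB: int) -> tuple[float, float]:
    """1-df chi-squared goodness of fit to Hardy-Weinberg proportions.

    Allele frequencies are estimated from the genotype counts themselves,
    which costs one degree of freedom.  Monomorphic input returns (0, 1).
    """
    n = n_AA + n_AB + n_BB
    if n < 5:
        raise ValueError("need at least 5 genotyped subjects")
    p = (2 * n_AA + n_AB) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 0.0, 1.0
    expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
    observed = np.array([n_AA, n_AB, n_BB], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def adjust_bonferroni(
    p_values: list[float], m: int | None = None, alpha: float = 0.05
) -> tuple[list[bool], float]:
    """Bonferroni decisions: significant iff p < alpha / m.

    ``m`` defaults to the number of tests supplied; it may be larger when
    the analysis batch includes tests reported elsewhere.
    """
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise ValueError("m must be at least the number of tests")
    threshold = alpha / m
    return [p < threshold for p in p_values], threshold


# ---------------------------------------------------------------------------
# pipeline over tidy allele-count frames (synthetic_data dialect)


def run_dae(
    allele_counts: pd.DataFrame,
    het_band: tuple[float, float] = (0.25, 0.75),
    unmatched_band: tuple[float, float] = (0.10, 0.90),
    hom_max: float = 0.05,
    min_reads: int = 20,
    alpha: float = 0.05,
    matched_only: bool = False,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Per-site DAE F tests from a tidy allele-count frame.

    Expects columns subject_id, site_id, material, count_A, count_B (a
    ``gene`` column is carried through if present).  For each site the gDNA
    records define heterozygotes; cDNA ratios come from subjects with a
    matched gDNA het call, plus — unless ``matched_only`` — unmatched cDNA
    samples called heterozygous from their own counts with the wider,
    lower-confidence ``unmatched_band``.  All gDNA heterozygotes are pooled
    as the analytic-noise control.
    """
    need = {"subject_id", "site_id", "material", "count_A", "count_B"}
    if not need <= set(allele_counts.columns):
        raise ValueError(f"allele count frame missing {sorted(need - set(allele_counts.columns))}")
    has_gene = "gene" in allele_counts.columns
    results = []
    for site_id, grp in allele_counts.groupby("site_id", sort=True):
        gene = str(grp["gene"].iloc[0]) if has_gene else ""
        gdna_calls: dict[str, str] = {}
        gdna_ratios = []
        for row in grp[grp["material"] == "gDNA"].itertuples(index=False):
            rec = AlleleCountRecord(
                str(row.subject_id), str(site_id), "gDNA",
                int(row.count_A), int(row.count_B),
            )
            if rec.total < min_reads:
                continue
            call = call_genotype(rec, het_band, hom_max)
            gdna_calls[rec.subject_id] = call.call
            if call.call == "het" and rec.count_A > 0 and rec.count_B > 0:
                gdna_ratios.append(log2_ratio(rec))
        cdna_ratios = []
        for row in grp[grp["material"] == "cDNA"].itertuples(index=False):
            rec = AlleleCountRecord(
                str(row.subject_id), str(site_id), "cDNA",
                int(row.count_A), int(row.count_B),
            )
            if rec.total < min_reads:
                continue
            matched = gdna_calls.get(rec.subject_id)
            if matched is not None:
                is_het = matched == "het"
            elif matched_only:
                continue
            else:  # lower-confidence self-call on cDNA counts
                lo, hi = unmatched_band
                is_het = lo <= rec.minor_fraction <= hi
            if is_het and rec.count_A > 0 and rec.count_B > 0:
                cdna_ratios.append(log2_ratio(rec))
        if len(cdna_ratios) < 3 or len(gdna_ratios) < 3:
            continue
        results.append(
            dae_f_test(
                np.array(cdna_ratios), np.array(gdna_ratios),
                site_id=str(site_id), gene=gene, two_sided=two_sided,
            )
        )
    if not results:
        return pd.DataFrame(
            columns=["site_id", "gene", "n_het_cdna", "n_het_gdna",
                     "var_cdna", "var_gdna", "F", "p", "p_adjusted",
                     "significant", "bonferroni_threshold"]
        )
    decisions, threshold = adjust_bonferroni([r.p for r in results], alpha=alpha)
    out = pd.DataFrame(
        {
            "site_id": [r.site_id for r in results],
            "gene": [r.gene for r in results],
            "n_het_cdna": [r.n_het_cdna for r in results],
            "n_het_gdna": [r.n_het_gdna for r in results],
            "var_cdna": [r.var_cdna for r in results],
            "var_gdna": [r.var_gdna for r in results],
            "F": [r.F for r in results],
            "p": [r.p for r in results],
            "p_adjusted": [min(1.0, r.p * len(results)) for r in results],
            "significant": decisions,
            "bonferroni_threshold": threshold,
        }
    )
    return out
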