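"""Internal-standard based absolute quantification of targeted amplicon counts.

Each assay co-amplifies the native transcript with a known number of
internal-standard (IS) molecules spiked into the reaction.  Because both
templates compete for the same primers, the native/IS read-count ratio
estimates the number of native molecules loaded, independent of per-assay
amplification efficiency and sequencing depth:

    molecules = spike * native_reads / is_reads

Abundances are then expressed as target molecules per 10^6 ACTB molecules,
which removes variation in cDNA input between samples.  Cells are filtered
when either read count is too low for the ratio to be stable (stochastic
sampling error), assays are dropped when measured in too few subjects, and
the remaining missing cells can be mean-imputed for downstream multivariate
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssayDef",
    "AbundanceMatrix",
    "FilterResult",
    "compute_molecules",
    "normalize_to_actb",
    "stochastic_filter",
    "representation_filter",
    "mean_impute",
    "integrity_ratio",
    "counts_to_abundance",
    "read_counts_tsv",
    "write_abundance_tsv",
    "read_abundance_tsv",
]

# provenance / reason codes for matrix cells
MEASURED = "measured"
FILTERED_LOW_COUNT = "filtered_low_count"
IMPUTED = "imputed"
SAMPLE_FAIL = "sample_fail"
NOT_MEASURED = "not_measured"

# reason codes for stochastic_filter failures
NATIVE_LOW = "native_low"
IS_LOW = "IS_low"


@dataclass(frozen=True)
class AssayDef:
    """One targeted amplicon assay.

    ``is_spike_molecules`` is the number of internal-standard molecules
    spiked per reaction for this assay.  ``site_id`` names the transcribed
    SNP measured by the assay, if any.  ``distance_class`` marks assays used
    by the 5'/3' RNA-integrity ratio.
    """

    assay_id: str
    gene: str
    is_spike_molecules: float
    site_id: str | None = None
    distance_class: str = "other"  # {5prime, 3prime, other}

    def __post_init__(self) -> None:
        if self.is_spike_molecules <= 0:
            raise ValueError(
                f"assay {self.assay_id}: is_spike_molecules must be > 0"
            )
        if self.distance_class not in ("5prime", "3prime", "other"):
            raise ValueError(f"bad distance_class {self.distance_class!r}")


@dataclass
class AbundanceMatrix:
    """Subjects x assays absolute abundance (molecules per 10^6 ACTB molecules).

    ``values`` holds NaN where the cell is missing; ``flags`` carries a
    provenance/reason code per cell (measured, filtered_low_count, imputed,
    sample_fail, not_measured).
    """

    values: pd.DataFrame
    flags: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.flags.index) or not (
            self.values.columns.equals(self.flags.columns)
        ):
            raise ValueError("values and flags must share index and columns")
        present = self.values.to_numpy()
        if np.nanmin(present, initial=0.0) < 0:
            raise ValueError("abundance must be non-negative where present")

    @property
    def subjects(self) -> list[str]:
        return list(self.values.index)

    @property
    def assays(self) -> list[str]:
        return list(self.values.columns)

    def measured_fraction(self) -> pd.Series:
        """Fraction of subjects with a measured (non-missing) value per assay."""
        return self.values.notna().mean(axis=0)

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.copy(), self.flags.copy())


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reason: str | None = None

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


def compute_molecules(
    native_reads: float, is_reads: float, spike: float
) -> float:
    """Native molecules loaded, from the native/IS read ratio.

    Returns NaN (missing, not an exception) when no IS reads were observed,
    since the ratio is then undefined.
    """
    if spike <= 0:
        raise ValueError("spike must be > 0 molecules")
    if native_reads < 0 or is_reads < 0:
        raise ValueError("read counts must be non-negative")
    if is_reads == 0:
        return float("nan")
    return spike * native_reads / is_reads


def normalize_to_actb(target_molecules: float, actb_molecules: float) -> float:
    """Express target molecules per 10^6 ACTB molecules."""
    if actb_molecules <= 0:
        raise ValueError("ACTB molecules must be > 0; sample fails QC")
    return 1e6 * target_molecules / actb_molecules


def stochastic_filter(
    native_reads: float, is_reads: float, min_reads: int = 20
) -> FilterResult:
    """Require both templates to reach ``min_reads`` reads.

    Below ~20 reads the Poisson sampling CV of a count exceeds ~22%, so the
    native/IS ratio is dominated by stochastic sampling error.  The IS count
    is checked first: without adequate IS reads the ratio denominator is
    unreliable regardless of native signal.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if is_reads < min_reads:
        return FilterResult(False, IS_LOW)
    if native_reads < min_reads:
        return FilterResult(False, NATIVE_LOW)
    return FilterResult(True, None)


def representation_filter(
    matrix: AbundanceMatrix, min_fraction: float = 0.70
) -> list[str]:
    """Assays measured in at least ``min_fraction`` of subjects (inclusive)."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if matrix.values.empty:
        raise ValueError("empty abundance matrix")
    frac = matrix.measured_fraction()
    return [a for a in matrix.assays if frac[a] >= min_fraction]


def retained_gene_count(retained: Sequence[str], assays: Iterable[AssayDef]) -> int:
    genes = {a.gene for a in assays if a.assay_id in set(retained)}
    return len(genes)


def mean_impute(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Replace missing cells with the per-assay mean of measured cells.

    Imputed cells are flagged ``imputed``; an all-missing assay is an error
    (it should have been removed by :func:`representation_filter`).
    """
    out = matrix.copy()
    for assay in out.assays:
        col = out.values[assay]
        if col.isna().all():
            raise ValueError(f"assay {assay} has no measured values; filter first")
        missing = col.isna()
        if missing.any():
            out.values.loc[missing, assay] = col.mean()
            out.flags.loc[missing, assay] = IMPUTED
    return out


def integrity_ratio(
    matrix: AbundanceMatrix,
    five_assay: str,
    three_assay: str,
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Per-subject 5'/3' abundance ratio for one gene, as an RNA-integrity QC.

    cDNA is primed from the poly-A tail, so degraded (short) RNA depresses
    signal at assays far from the 3' end; a low 5'/3' ratio therefore flags
    degradation.  Subjects with ratio below ``threshold``, or with no 3'
    signal, are flagged.
    """
    for a in (five_assay, three_assay):
        if a not in matrix.assays:
            raise KeyError(f"assay {a} not in matrix")
    five = matrix.values[five_assay]
    three = matrix.values[three_assay]
    ratio = five / three.where(three > 0)
    flagged = ratio.isna() | (ratio < threshold)
    return pd.DataFrame({"ratio": ratio, "flagged": flagged})


# ---------------------------------------------------------------------------
# pipeline: long read-count table -> AbundanceMatrix


def counts_to_abundance(
    counts: pd.DataFrame,
    assays: Sequence[AssayDef],
    actb_assay: str = "ACTB_3p",
    min_reads: int = 20,
) -> AbundanceMatrix:
    """Assemble the analysis-ready abundance matrix from raw counts.

    ``counts`` is the long table dialect (subject_id, assay_id, site_id,
    material, template, allele, reads).  Only cDNA total-count rows are
    used here.  ACTB is quantified first from its own IS; if the ACTB assay
    itself fails the stochastic filter the whole sample is flagged
    ``sample_fail`` and every cell of that subject is missing.
    """
    by_id = {a.assay_id: a for a in assays}
    if actb_assay not in by_id:
        raise KeyError(f"ACTB assay {actb_assay!r} not among assay definitions")
    total = counts[
        (counts["material"] == "cDNA") & (counts["allele"] == "total")
    ]
    wide = total.pivot_table(
        index=["subject_id", "assay_id"],
        columns="template",
        values="reads",
        aggfunc="sum",
        fill_value=0,
    )
    for col in ("native", "IS"):
        if col not in wide.columns:
            wide[col] = 0
    subjects = sorted(total["subject_id"].unique())
    assay_ids = [a.assay_id for a in assays]
    values = pd.DataFrame(np.nan, index=subjects, columns=assay_ids)
    flags = pd.DataFrame(NOT_MEASURED, index=subjects, columns=assay_ids)

    for subj in subjects:
        sub = wide.loc[subj] if subj in wide.index.get_level_values(0) else None
        if sub is None:
            flags.loc[subj, :] = SAMPLE_FAIL
            continue

        def reads_for(assay_id: str) -> tuple[float, float]:
            if assay_id not in sub.index:
                return 0.0, 0.0
            row = sub.loc[assay_id]
            return float(row["native"]), float(row["IS"])

        a_native, a_is = reads_for(actb_assay)
        if not stochastic_filter(a_native, a_is, min_reads).passed:
            flags.loc[subj, :] = SAMPLE_FAIL
            continue
        actb_mol = compute_molecules(a_native, a_is, by_id[actb_assay].is_spike_molecules)

        for assay_id in assay_ids:
            native, is_reads = reads_for(assay_id)
            res = stochastic_filter(native, is_reads, min_reads)
            if not res.passed:
                flags.loc[subj, assay_id] = FILTERED_LOW_COUNT
                continue
            mol = compute_molecules(native, is_reads, by_id[assay_id].is_spike_molecules)
            values.loc[subj, assay_id] = normalize_to_actb(mol, actb_mol)
            flags.loc[subj, assay_id] = MEASURED
    return AbundanceMatrix(values, flags)


# ---------------------------------------------------------------------------
# I/O helpers

COUNT_COLUMNS = [
    "subject_id",
    "assay_id",
    "site_id",
    "material",
    "template",
    "allele",
    "reads",
]


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "assay_id": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    return df


def write_abundance_tsv(matrix: AbundanceMatrix, path) -> None:
    matrix.values.rename_axis("subject_id").to_csv(path, sep="\t")


def read_abundance_tsv(path) -> AbundanceMatrix:
    """Load a wide abundance TSV (e.g. a supplementary-table export).

    All present cells are flagged ``measured``; NaN cells ``not_measured``.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    flags = pd.DataFrame(
        np.where(values.notna(), MEASURED, NOT_MEASURED),
        index=values.index,
        columns=values.columns,
    )
    return AbundanceMatrix(values, flags)
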