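"""Synthetic targeted-RNAseq study generator.

Emulates a two-cohort bronchial-epithelial-cell expression study measured by
competitive internal-standard amplicon sequencing: 30 COPD and 30 control
subjects, a 68-assay / 35-gene panel, group mean shifts on a small set of
disease-associated genes, a denser correlation structure in the COPD cohort,
abundance-driven missingness, and paired cDNA/gDNA allele counts at
transcribed SNPs with tunable cis-regulatory effects.

The generative model, briefly:

* per-subject latent log2 abundance ~ MVN(mu + cohort shift, Sigma), where
  Sigma has within-gene correlation blocks and, for the COPD cohort, extra
  user-specified gene-pair correlations;
* read counts: a per-reaction Gamma amplification factor is shared by the
  native and internal-standard template (they compete for the same primers
  in the same reaction), with Poisson sampling on top — marginally each
  count is negative binomial, but the native/IS ratio carries Poisson-only
  noise, which is the point of competitive internal standards;
* assays whose latent molecule count falls below ``dropout_threshold`` emit
  zero native reads (low-expression dropout, the study's stated missingness
  mechanism — not missing-at-random);
* allele counts at heterozygous sites: gDNA allele fraction tight around
  0.5 (logit-normal analytic noise); cDNA allele fraction shifted on the
  logit scale by ``beta * g`` where g = +/-1 is the unobserved phase of a
  linked regulatory allele.  Across heterozygous subjects this inflates the
  variance of the cDNA log2 allelic ratio relative to gDNA, which is
  exactly what the downstream variance F-test detects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .quantify import AssayDef

__all__ = [
    "CisSite",
    "SimulationConfig",
    "SubjectRecord",
    "default_assay_panel",
    "simulate_cohort",
    "simulate_allele_counts",
    "allele_counts_to_long",
    "ground_truth",
]

# Antioxidant / DNA-repair / cell-cycle-control panel genes; ACTB is the
# normalizer and carries the 5'/3' integrity assay pair.
CLASSIFIER_GENES = ("CAT", "CEBPG", "GPX1", "KEAP1", "TP73", "XPA")

_TARGET_GENES = (
    "CAT", "CEBPG", "GPX1", "KEAP1", "TP73", "XPA",
    "ERCC5", "TP53", "CEBPD", "CEBPA", "CEBPB", "NFE2L2",
    "OGG1", "XRCC1", "XRCC3", "XRCC4", "XRCC5", "CDKN1A",
    "GSTM1", "GSTT1", "GSTP1", "SOD1", "SOD2", "SOD3",
    "GPX3", "ERCC1", "ERCC2", "ERCC4", "XPC", "MDM2",
    "E2F1", "CCND1", "RB1", "ATM",
)

_DAE_SITES = {
    "CAT": "rs1049982",
    "CEBPG": "rs3745968",
    "KEAP1": "rs1048287",
    "TP73": "rs1801174",
    "ERCC5": "rs17655",
}


def default_assay_panel(spike_molecules: float = 1e4) -> list[AssayDef]:
    """68 assays on 35 genes: ACTB 5'/3' pair + 1-2 assays per target gene."""
    assays: list[AssayDef] = [
        AssayDef("ACTB_5p", "ACTB", spike_molecules, distance_class="5prime"),
        AssayDef("ACTB_3p", "ACTB", spike_molecules, distance_class="3prime"),
    ]
    for i, gene in enumerate(_TARGET_GENES):
        assays.append(
            AssayDef(f"{gene}_1", gene, spike_molecules, site_id=_DAE_SITES.get(gene))
        )
        if i < 32:  # first 32 genes get a second assay -> 2 + 34 + 32 = 68
            assays.append(AssayDef(f"{gene}_2", gene, spike_molecules))
    return assays


@dataclass(frozen=True)
class CisSite:
    """A transcribed SNP with a linked cis-regulatory effect.

    ``maf`` is the minor-allele frequency (0, 0.5]; ``beta`` the logit-scale
    allelic shift of the cDNA allele fraction in heterozygotes.
    """

    maf: float
    beta: float

    def __post_init__(self) -> None:
        if not 0 <= self.maf <= 0.5:
            raise ValueError("maf must lie in [0, 0.5]")
        if self.maf == 0 and self.beta != 0:
            raise ValueError("cis effect requested at a monomorphic site (maf=0)")


def _default_cis_sites() -> dict[str, CisSite]:
    return {
        "rs1049982": CisSite(0.34, 0.6),   # CAT promoter region SNP
        "rs3745968": CisSite(0.20, 0.6),   # CEBPG
        "rs1048287": CisSite(0.115, 0.6),  # KEAP1
        "rs1801174": CisSite(0.25, 0.6),   # TP73
        "rs17655": CisSite(0.45, 0.6),     # ERCC5 3'UTR
    }


def _default_de_genes() -> dict[str, float]:
    # one assay per classifier gene carries the COPD mean shift (log2 units);
    # 0.38 at subject SD 0.8 yields a cross-validated AUC near 0.75 at n=30+30
    return {f"{g}_1": 0.38 for g in CLASSIFIER_GENES}


def _default_extra_correlations() -> list[tuple[str, str, float]]:
    """Denser COPD wiring: a shared pathway-activity factor.

    In the COPD cohort every primary target assay loads on one latent
    stress/inflammation activity factor, giving a uniform extra pairwise
    correlation of 0.30 among the 34 primary assays.  A factor structure is
    positive definite by construction no matter how many genes it touches,
    and it reproduces the qualitative observation that the case cohort's
    co-expression network is much denser than the control network.
    """
    primary = [f"{g}_1" for g in _TARGET_GENES]
    pairs = [
        (primary[i], primary[j], 0.30)
        for i in range(len(primary))
        for j in range(i + 1, len(primary))
    ]
    return pairs


@dataclass
class SimulationConfig:
    n_copd: int = 30
    n_control: int = 30
    seed: int = 0
    depth_mean: float = 3000.0          # expected IS reads per assay
    is_spike_molecules: float = 1e4     # IS molecules per reaction
    assays: list[AssayDef] | None = None
    de_genes: dict[str, float] = field(default_factory=_default_de_genes)
    copd_extra_correlations: list[tuple[str, str, float]] = field(
        default_factory=_default_extra_correlations
    )
    cis_sites: dict[str, CisSite] = field(default_factory=_default_cis_sites)
    gdna_overdispersion: float = 0.15   # logit-scale analytic SD
    dropout_threshold: float = 4500.0   # molecules; below -> zero native reads
    n_dae_subjects: int = 160           # archival subjects for allele counting
    allele_depth_mean: float = 3000.0   # expected reads per allele-count assay
    sigma_subject: float = 0.8          # biological SD of log2 abundance
    sigma_actb: float = 0.1             # residual SD of the housekeeping gene
    input_scale_sd: float = 0.5         # per-subject cDNA input factor (log2)
    within_gene_r: float = 0.40
    nb_dispersion: float = 0.05

    def __post_init__(self) -> None:
        if self.n_copd <= 0 or self.n_control <= 0:
            raise ValueError("cohort sizes must be positive")
        if self.depth_mean <= 0 or self.is_spike_molecules <= 0:
            raise ValueError("depth and spike must be positive")
        for a, b, r in self.copd_extra_correlations:
            if not -1 < r < 1:
                raise ValueError(f"extra correlation ({a},{b}) r={r} outside (-1,1)")
        if self.assays is None:
            self.assays = default_assay_panel(self.is_spike_molecules)

    @property
    def assay_ids(self) -> list[str]:
        return [a.assay_id for a in self.assays]


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    age: float
    sex: str                 # {male, female}
    pack_years: float
    smoking_status: str      # {current, former}
    fev1_fvc: float
    fev1_pct: float
    cohort: str              # {COPD, control}

    def __post_init__(self) -> None:
        is_copd = self.fev1_fvc < 0.7 and self.fev1_pct < 80
        if (self.cohort == "COPD") != is_copd:
            raise ValueError(
                f"{self.subject_id}: spirometry inconsistent with cohort label"
            )


# ---------------------------------------------------------------------------


def _baseline_log2(config: SimulationConfig) -> pd.Series:
    """Deterministic per-assay baseline log2 molecules.

    ACTB is abundant.  Primary (gene_1) assays target well-expressed
    transcript regions; secondary (gene_2) assays span ~2 decades so the
    least expressed fall under the dropout threshold in part of the cohort,
    reproducing low-expression missingness.  Signal assays sit in the
    upper-middle range so disease signal is not confounded with
    missingness.  Assays outside the default naming scheme get a fixed
    mid-range baseline.
    """
    ids = config.assay_ids
    mu = pd.Series(13.5, index=ids)  # fallback for nonstandard assay names
    actb = [a for a in ids if a.startswith("ACTB")]
    primary = [a for a in ids if a.endswith("_1") and a not in actb]
    secondary = [a for a in ids if a.endswith("_2") and a not in actb]

    def stride_spread(names: list[str], lo: float, hi: float) -> None:
        if not names:
            return
        spread = np.linspace(lo, hi, len(names))
        # fixed stride shuffle decouples abundance rank from panel order
        order = np.argsort([(7 * i) % len(names) for i in range(len(names))])
        for a, m in zip(names, spread[order]):
            mu[a] = m

    # primary assays target well-expressed transcript regions (panel design);
    # secondary assays span the dropout range, so roughly half fail the
    # representation filter, as in a real panel
    stride_spread(primary, 12.8, 16.0)
    stride_spread(secondary, 9.0, 16.0)
    for sig in _default_de_genes():
        if sig in mu.index:
            mu[sig] = max(mu[sig], 13.2)
    for a in actb:
        # 3' assay slightly above 5' (oligo-dT priming; partial degradation)
        mu[a] = 17.5 if a.endswith("3p") else 17.0
    return mu


def _correlation_matrix(
    config: SimulationConfig, cohort: str
) -> np.ndarray:
    ids = config.assay_ids
    idx = {a: i for i, a in enumerate(ids)}
    p = len(ids)
    corr = np.eye(p)
    gene_of = {a.assay_id: a.gene for a in config.assays}
    for i, a in enumerate(ids):
        for j in range(i + 1, p):
            if gene_of[a] == gene_of[ids[j]]:
                corr[i, j] = corr[j, i] = config.within_gene_r
    if cohort == "COPD":
        for a, b, r in config.copd_extra_correlations:
            if a not in idx or b not in idx:
                raise KeyError(f"extra correlation names unknown assay: ({a}, {b})")
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    w = np.linalg.eigvalsh(corr)
    if w.min() <= 1e-10:
        pairs = ", ".join(f"({a},{b},r={r})" for a, b, r in config.copd_extra_correlations)
        raise ValueError(
            f"implied {cohort} correlation matrix is not positive definite "
            f"(min eigenvalue {w.min():.3g}); check extra correlation pairs {pairs}"
        )
    return corr


def _draw_demographics(config: SimulationConfig, rng: np.random.Generator) -> list[SubjectRecord]:
    subjects: list[SubjectRecord] = []
    plans = [
        ("control", config.n_control, 11 / 30, 10 / 30, 64.3, 49.0),
        ("COPD", config.n_copd, 22 / 30, 9 / 30, 63.6, 60.0),
    ]
    k = 0
    for cohort, n, p_male, p_current, age_mu, py_mu in plans:
        for _ in range(n):
            k += 1
            sex = "male" if rng.random() < p_male else "female"
            smoking = "current" if rng.random() < p_current else "former"
            age = float(np.clip(rng.normal(age_mu, 5.0), 50, 85))
            pack_years = float(np.clip(rng.normal(py_mu, 18.0), 20, 150))
            if cohort == "COPD":
                fev1_fvc = float(np.clip(rng.normal(0.53, 0.08), 0.30, 0.699))
                fev1_pct = float(np.clip(rng.normal(55, 12), 25, 79.9))
            else:
                fev1_fvc = float(np.clip(rng.normal(0.81, 0.04), 0.701, 0.95))
                fev1_pct = float(np.clip(rng.normal(95, 10), 80.1, 130))
            subjects.append(
                SubjectRecord(
                    subject_id=f"S{k:03d}",
                    age=age,
                    sex=sex,
                    pack_years=pack_years,
                    smoking_status=smoking,
                    fev1_fvc=fev1_fvc,
                    fev1_pct=fev1_pct,
                    cohort=cohort,
                )
            )
    return subjects


def _amplification_factors(
    rng: np.random.Generator, n: int, dispersion: float
) -> np.ndarray:
    """Per-reaction amplification factors, Gamma with mean 1.

    Native and IS template co-amplify in the same reaction with the same
    primers, so the amplification factor is shared between them and cancels
    in their ratio; marginally each read count is negative binomial with
    Var = m + dispersion * m^2.
    """
    if dispersion <= 0:
        return np.ones(n)
    return rng.gamma(1.0 / dispersion, dispersion, size=n)


def _poisson_reads(rng: np.random.Generator, mean: np.ndarray) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    out[pos] = rng.poisson(mean[pos])
    return out


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[SubjectRecord], pd.DataFrame, pd.DataFrame]:
    """Draw subjects, latent abundances, and the long read-count table.

    Returns ``(subjects, latent, counts)`` where ``latent`` is the
    subjects x assays matrix of true molecules per reaction and ``counts``
    is the long TSV dialect consumed by the quantification pipeline.
    """
    rng = np.random.default_rng(config.seed)
    subjects = _draw_demographics(config, rng)
    ids = config.assay_ids
    mu = _baseline_log2(config)

    chol = {
        cohort: np.linalg.cholesky(_correlation_matrix(config, cohort))
        for cohort in ("control", "COPD")
    }
    shift = pd.Series(0.0, index=ids)
    for assay, delta in config.de_genes.items():
        if assay not in shift.index:
            raise KeyError(f"de_genes names unknown assay {assay!r}")
        shift[assay] = delta

    rows = []
    latent_rows = []
    site_of = {a.assay_id: (a.site_id or "") for a in config.assays}
    spike_of = {a.assay_id: a.is_spike_molecules for a in config.assays}
    spikes = np.array([spike_of[a] for a in ids])
    # targets carry the full biological SD; the normalizer gene varies little
    # of its own (housekeeping), while a per-subject cDNA input factor scales
    # every assay jointly and cancels on normalization
    sigma = np.array(
        [config.sigma_actb if a.startswith("ACTB") else config.sigma_subject
         for a in ids]
    )
    for subj in subjects:
        z = chol[subj.cohort] @ rng.standard_normal(len(ids))
        log2_ab = mu.to_numpy() + sigma * z
        if subj.cohort == "COPD":
            log2_ab = log2_ab + shift.to_numpy()
        log2_ab = log2_ab + rng.normal(0.0, config.input_scale_sd)
        molecules = np.exp2(log2_ab)
        latent_rows.append(molecules)

        amp = _amplification_factors(rng, len(ids), config.nb_dispersion)
        is_mean = amp * config.depth_mean
        native_mean = amp * config.depth_mean * molecules / spikes
        native_mean[molecules < config.dropout_threshold] = 0.0  # dropout
        is_reads = _poisson_reads(rng, is_mean)
        native_reads = _poisson_reads(rng, native_mean)
        for j, assay in enumerate(ids):
            rows.append(
                (subj.subject_id, assay, site_of[assay], "cDNA", "native",
                 "total", int(native_reads[j]))
            )
            rows.append(
                (subj.subject_id, assay, site_of[assay], "cDNA", "IS",
                 "total", int(is_reads[j]))
            )

    latent = pd.DataFrame(
        latent_rows, index=[s.subject_id for s in subjects], columns=ids
    )
    counts = pd.DataFrame(
        rows,
        columns=["subject_id", "assay_id", "site_id", "material", "template",
                 "allele", "reads"],
    )
    return subjects, latent, counts


# ---------------------------------------------------------------------------
# allele counts


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def _inv_logit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_allele_counts(
    config: SimulationConfig, subjects: Sequence[str] | None = None
) -> pd.DataFrame:
    """Paired cDNA/gDNA allele counts at each configured transcribed SNP.

    ``subjects`` defaults to ``n_dae_subjects`` synthetic ids (the allele
    analysis cohort is larger than the classifier cohort, mirroring the use
    of archival samples).  Genotypes are drawn at Hardy-Weinberg proportions
    from the site's minor-allele frequency; allele A is the major allele.

    Returns a tidy frame: subject_id, site_id, gene, material, count_A,
    count_B, genotype.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x5EED]).generate_state(1)[0]
    )
    if subjects is None:
        subjects = [f"D{k:03d}" for k in range(1, config.n_dae_subjects + 1)]
    gene_of_site = {
        a.site_id: a.gene for a in config.assays if a.site_id is not None
    }
    rows = []
    for site_id, site in config.cis_sites.items():
        gene = gene_of_site.get(site_id, "")
        q = site.maf
        for subj in subjects:
            u = rng.random()
            if u < (1 - q) ** 2:
                genotype = "AA"
            elif u < (1 - q) ** 2 + 2 * q * (1 - q):
                genotype = "AB"
            else:
                genotype = "BB"
            for material, shift_sd in (
                ("gDNA", config.gdna_overdispersion),
                ("cDNA", config.gdna_overdispersion),
            ):
                depth = rng.poisson(config.allele_depth_mean)
                if genotype == "AA":
                    a_count, b_count = depth, 0
                elif genotype == "BB":
                    a_count, b_count = 0, depth
                else:
                    eta = rng.normal(0.0, shift_sd)
                    if material == "cDNA" and site.beta != 0:
                        phase = 1.0 if rng.random() < 0.5 else -1.0
                        eta += site.beta * phase
                    p_a = float(_inv_logit(np.array([eta]))[0])
                    a_count = int(rng.binomial(depth, p_a)) if depth > 0 else 0
                    b_count = depth - a_count
                rows.append(
                    (subj, site_id, gene, material, a_count, b_count, genotype)
                )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "site_id", "gene", "material", "count_A",
                 "count_B", "genotype"],
    )


def allele_counts_to_long(allele_counts: pd.DataFrame) -> pd.DataFrame:
    """Convert tidy allele counts to the long count-table dialect."""
    rows = []
    for rec in allele_counts.itertuples(index=False):
        for allele, n in (("A", rec.count_A), ("B", rec.count_B)):
            rows.append(
                (rec.subject_id, "", rec.site_id, rec.material, "native",
                 allele, int(n))
            )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "assay_id", "site_id", "material", "template",
                 "allele", "reads"],
    )


def ground_truth(config: SimulationConfig) -> dict:
    """JSON-serializable record of the generating parameters."""
    return {
        "seed": config.seed,
        "n_copd": config.n_copd,
        "n_control": config.n_control,
        "de_genes": dict(config.de_genes),
        "copd_extra_correlations": [
            list(t) for t in config.copd_extra_correlations
        ],
        "cis_sites": {
            s: {"maf": c.maf, "beta": c.beta} for s, c in config.cis_sites.items()
        },
        "dropout_threshold": config.dropout_threshold,
        "depth_mean": config.depth_mean,
        "is_spike_molecules": config.is_spike_molecules,
    }


def subjects_to_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in subjects]).set_index("subject_id")
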