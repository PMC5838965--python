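"""End-to-end convenience wrapper: synthetic study -> all analysis outputs.

Glue only; every statistic lives in its own module.  Mirrors the analysis
order of a targeted-RNAseq cohort study: quantify, filter, build per-cohort
networks on the measured (pre-imputation) matrix, impute, classify.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classifier, network, quantify, simulate

__all__ = ["StudyResult", "run_study", "assemble_features"]


@dataclass
class StudyResult:
    config: simulate.SimulationConfig
    meta: pd.DataFrame
    latent: pd.DataFrame
    matrix: quantify.AbundanceMatrix          # retained assays, not imputed
    imputed: quantify.AbundanceMatrix
    retained_assays: list[str]
    retained_genes: int
    networks: dict[str, network.CorrelationNetwork]
    node_metrics: dict[str, pd.DataFrame]
    network_comparison: pd.DataFrame
    features: pd.DataFrame                    # log10 abundance + demographics
    labels: np.ndarray
    cv_report: classifier.CVReport


def assemble_features(
    imputed: quantify.AbundanceMatrix,
    meta: pd.DataFrame,
    demographics: bool = True,
) -> pd.DataFrame:
    """log10 feature matrix; demographic covariates on their natural scales."""
    X = imputed.values.copy()
    floors = X.where(X > 0).min()
    X = X.apply(lambda c: np.log10(c.where(c > 0, floors[c.name] / 2)))
    if demographics:
        X["sex"] = (meta.loc[X.index, "sex"] == "male").astype(float)
        X["age"] = meta.loc[X.index, "age"].astype(float)
        X["pack_years"] = meta.loc[X.index, "pack_years"].astype(float)
    return X


def run_study(
    config: simulate.SimulationConfig | None = None,
    seed: int = 0,
    min_fraction: float = 0.70,
    cv_seed: int = 17,
    demographics: bool = True,
    candidate_sizes: list[int] | None = None,
) -> StudyResult:
    """Simulate one study and run quantification, networks, and classifier."""
    if config is None:
        config = simulate.SimulationConfig(seed=seed)
    subjects, latent, counts = simulate.simulate_cohort(config)
    meta = simulate.subjects_to_frame(subjects)
    full = quantify.counts_to_abundance(counts, config.assays)
    retained = [
        a for a in quantify.representation_filter(full, min_fraction)
        if not a.startswith("ACTB")  # the normalizer is not an analyte
    ]
    matrix = quantify.AbundanceMatrix(full.values[retained], full.flags[retained])
    imputed = quantify.mean_impute(matrix)

    networks_, metrics = {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cohort in ("control", "COPD"):
            subs = [s.subject_id for s in subjects if s.cohort == cohort]
            networks_[cohort] = network.pearson_edges(matrix, subs)
            metrics[cohort] = network.centrality(networks_[cohort])
    comparison = network.compare_networks(metrics["COPD"], metrics["control"])

    X = assemble_features(imputed, meta, demographics=demographics)
    y = meta["cohort"].to_numpy()
    report = classifier.cv_pooled_roc(
        X, y, k=10, seed=cv_seed, pos_label="COPD",
        candidate_sizes=candidate_sizes,
    )
    return StudyResult(
        config=config,
        meta=meta,
        latent=latent,
        matrix=matrix,
        imputed=imputed,
        retained_assays=retained,
        retained_genes=quantify.retained_gene_count(retained, config.assays),
        networks=networks_,
        node_metrics=metrics,
        network_comparison=comparison,
        features=X,
        labels=y,
        cv_report=report,
    )
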