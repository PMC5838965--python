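"""Shrinkage linear discriminant analysis (SLDA) with CAT-score ranking.

With ~35 features and 60 subjects, sample covariance matrices are noisy and
near-singular, so plain LDA overfits.  SLDA stabilizes both pieces of the
covariance by James-Stein-type shrinkage:

* per-feature pooled variances are shrunk toward their median,
  ``v_k = lam_v * median(s^2) + (1 - lam_v) * s_k^2``;
* the feature correlation matrix is shrunk toward the identity,
  ``R* = (1 - lam) * R + lam * I``,

with analytic, variance-minimizing shrinkage intensities (clipped to
[0, 1]) estimated from the data.  Features are ranked by the
correlation-adjusted t-score (CAT score)

    tau = (R*)^(-1/2) t,

the vector of shrunken two-sample t-scores decorrelated by the inverse
matrix square root of the shrunken correlation — a feature's |tau| measures
its contribution to class separation after accounting for its correlation
with the other features.  Model size is chosen by pooled k-fold
cross-validated ROC AUC, with feature ranking redone inside every training
fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "SLDAModel",
    "CVReport",
    "shrink_variances",
    "shrink_correlation_intensity",
    "shrunken_t_scores",
    "cat_scores",
    "fit_slda",
    "cv_pooled_roc",
    "auc_ci",
    "youden_cutpoint",
    "repeated_cv_cutpoint",
    "diagnostic_odds_ratio",
]


def _split_groups(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.unique(y)
    if labels.size != 2:
        raise ValueError(f"need exactly two classes, got {labels}")
    return X[y == labels[0]], X[y == labels[1]]


def _pooled_residuals(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Rows centered by their own group mean (pooled within-group residuals)."""
    E = np.empty_like(X, dtype=float)
    for lab in np.unique(y):
        mask = y == lab
        E[mask] = X[mask] - X[mask].mean(axis=0)
    return E


def shrink_variances(E: np.ndarray, df: int) -> tuple[np.ndarray, float]:
    """James-Stein shrinkage of per-feature variances toward their median.

    ``E`` holds group-centered residuals; ``df`` the pooled degrees of
    freedom (n - number of groups).  The intensity is the analytic
    estimator lam = sum Var(s_k^2) / sum (s_k^2 - median)^2, clipped to
    [0, 1]; it goes to 0 as n grows (no shrinkage needed) and to 1 when the
    empirical variances are indistinguishable from noise.
    """
    n = E.shape[0]
    if df < 1:
        raise ValueError("need pooled df >= 1")
    w = E**2
    s2 = w.sum(axis=0) / df
    target = float(np.median(s2))
    num = (n / (n - 1) ** 3) * ((w - w.mean(axis=0)) ** 2).sum(axis=0)
    den = ((s2 - target) ** 2).sum()
    lam = 1.0 if den == 0 else float(np.clip(num.sum() / den, 0.0, 1.0))
    v = lam * target + (1 - lam) * s2
    if np.any(v <= 0):
        raise ValueError("zero shrunken variance; drop constant features")
    return v, lam


def shrink_correlation_intensity(E: np.ndarray) -> tuple[np.ndarray, float]:
    """Shrunken residual correlation matrix R* = (1-lam) R + lam I.

    lam is the analytic variance-minimizing intensity
    lam = sum_{k<l} Var(r_kl) / sum_{k<l} r_kl^2, clipped to [0, 1].
    """
    n, p = E.shape
    if p == 1:
        return np.ones((1, 1)), 1.0
    sd = E.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = E / sd
    R = (Z.T @ Z) / n
    np.fill_diagonal(R, 1.0)
    # Var(r_kl) estimated from the spread of the per-subject products
    W = np.einsum("ik,il->kli", Z, Z)  # p x p x n products z_k z_l
    wbar = W.mean(axis=2)
    var_r = (n / (n - 1) ** 3) * ((W - wbar[:, :, None]) ** 2).sum(axis=2)
    off = ~np.eye(p, dtype=bool)
    den = (R[off] ** 2).sum()
    lam = 1.0 if den == 0 else float(np.clip(var_r[off].sum() / den, 0.0, 1.0))
    R_shrunk = (1 - lam) * R + lam * np.eye(p)
    return R_shrunk, lam


def shrunken_t_scores(
    X: np.ndarray, y: np.ndarray, lambda_var: float | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Two-sample t-scores with shrinkage-pooled variances.

    t_k = (mean_1k - mean_2k) / (sqrt(v_k) * sqrt(1/n1 + 1/n2)), v_k the
    shrunken pooled variance.  Returns (t, v, lam_v).  Group 1 is the first
    label in sorted order, so the sign convention is fixed.  Forcing
    ``lambda_var`` to 0 recovers the classical pooled-variance t exactly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    g1, g2 = _split_groups(X, y)
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per class")
    E = _pooled_residuals(X, y)
    df = n1 + n2 - 2
    v, lam_v = shrink_variances(E, df=df)
    if lambda_var is not None:
        s2 = (E**2).sum(axis=0) / df
        v = lambda_var * np.median(s2) + (1 - lambda_var) * s2
        lam_v = lambda_var
        if np.any(v <= 0):
            raise ValueError("zero shrunken variance; drop constant features")
    t = (g1.mean(axis=0) - g2.mean(axis=0)) / (np.sqrt(v) * np.sqrt(1 / n1 + 1 / n2))
    return t, v, lam_v


def _inv_sqrt(R: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root via eigendecomposition."""
    w, V = np.linalg.eigh(R)
    if w.min() <= 0:
        raise ValueError("correlation matrix not positive definite")
    return (V * (1.0 / np.sqrt(w))) @ V.T


def cat_scores(
    X: np.ndarray,
    y: np.ndarray,
    lambda_var: float | None = None,
    lambda_corr: float | None = None,
) -> np.ndarray:
    """Correlation-adjusted t-scores tau = (R*)^(-1/2) t.

    Forcing ``lambda_corr`` to 1 makes R* the identity, so tau equals the
    shrunken t-score vector exactly.
    """
    t, _, _ = shrunken_t_scores(X, y, lambda_var=lambda_var)
    if lambda_corr == 1.0:
        return t.copy()
    E = _pooled_residuals(np.asarray(X, dtype=float), np.asarray(y))
    R_shrunk, _ = shrink_correlation_intensity(E)
    if lambda_corr is not None:
        sd = E.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        Z = E / sd
        R = (Z.T @ Z) / len(y)
        np.fill_diagonal(R, 1.0)
        R_shrunk = (1 - lambda_corr) * R + lambda_corr * np.eye(E.shape[1])
    return _inv_sqrt(R_shrunk) @ t


@dataclass
class SLDAModel:
    features: list[str]
    labels: tuple            # (label_1, label_2) in sorted order
    means: np.ndarray        # 2 x p group means
    variances: np.ndarray    # shrunken pooled variances
    lambda_var: float
    lambda_corr: float
    R_shrunk: np.ndarray
    priors: np.ndarray       # empirical class priors
    pos_label: object = None # label treated as the "case" class

    def _discriminant(self, X: np.ndarray) -> np.ndarray:
        D = np.sqrt(self.variances)
        sigma = (D[:, None] * self.R_shrunk) * D[None, :]
        w = np.linalg.solve(sigma, self.means[0] - self.means[1])
        mid = 0.5 * (self.means[0] + self.means[1])
        return (X - mid) @ w + np.log(self.priors[0] / self.priors[1])

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """Posterior probability of the positive class."""
        X = np.asarray(X, dtype=float)
        d = self._discriminant(X)
        p1 = 1.0 / (1.0 + np.exp(-np.clip(d, -700, 700)))
        return p1 if self.pos_label == self.labels[0] else 1.0 - p1


def fit_slda(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    pos_label=None,
    lambda_var: float | None = None,
    lambda_corr: float | None = None,
) -> SLDAModel:
    """Fit the two-class shrinkage LDA on the given feature matrix.

    ``Sigma = D^(1/2) R* D^(1/2)`` with D the diagonal of shrunken pooled
    variances.  Forcing ``lambda_var`` / ``lambda_corr`` to 0 recovers
    classical pooled-covariance LDA (useful for oracle checks); forcing 1
    yields diagonal discriminant analysis.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = np.unique(y)
    if labels.size != 2:
        raise ValueError("two-class model")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    g1, g2 = X[y == labels[0]], X[y == labels[1]]
    means = np.vstack([g1.mean(axis=0), g2.mean(axis=0)])
    E = _pooled_residuals(X, y)
    df = len(y) - 2
    v, lam_v = shrink_variances(E, df)
    R_shrunk, lam_r = shrink_correlation_intensity(E)
    if lambda_var is not None:
        s2 = (E**2).sum(axis=0) / df
        v = lambda_var * np.median(s2) + (1 - lambda_var) * s2
        lam_v = lambda_var
    if lambda_corr is not None:
        sd = E.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        Z = E / sd
        R = (Z.T @ Z) / len(y)
        np.fill_diagonal(R, 1.0)
        R_shrunk = (1 - lambda_corr) * R + lambda_corr * np.eye(X.shape[1])
        lam_r = lambda_corr
    priors = np.array([len(g1), len(g2)], dtype=float) / len(y)
    if pos_label is None:
        pos_label = labels[0]
    return SLDAModel(
        features=list(feature_names),
        labels=tuple(labels),
        means=means,
        variances=v,
        lambda_var=lam_v,
        lambda_corr=lam_r,
        R_shrunk=R_shrunk,
        priors=priors,
        pos_label=pos_label,
    )


# ---------------------------------------------------------------------------
# cross-validation


def _stratified_folds(
    y: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold assignment (0..k-1 per subject), stratified by class."""
    assign = np.empty(len(y), dtype=int)
    for lab in np.unique(y):
        idx = np.flatnonzero(y == lab)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):  # classes smaller than k skip folds
            assign[i] = pos % k
    return assign


def _rank_features(X: np.ndarray, y: np.ndarray, names: list[str]) -> list[int]:
    """Indices ordered by decreasing |CAT score|; ties broken by name."""
    tau = cat_scores(X, y)
    order = sorted(range(len(names)), key=lambda i: (-abs(tau[i]), names[i]))
    return order


@dataclass
class CVReport:
    k: int
    seed: int
    fold_assignments: np.ndarray
    candidate_sizes: list[int]
    auc_by_size: dict[int, float]
    best_size: int
    posteriors: np.ndarray       # pooled out-of-fold posteriors, best size
    labels: np.ndarray
    auc: float
    selected_features: list[str] = field(default_factory=list)
    auc_ci: tuple[float, float] | None = None
    youden_threshold: float | None = None
    youden_j: float | None = None
    confusion: dict | None = None
    dor: float | None = None
    dor_ci: tuple[float, float] | None = None


def cv_pooled_roc(
    X: pd.DataFrame,
    y: np.ndarray,
    k: int = 10,
    candidate_sizes: list[int] | None = None,
    seed: int = 0,
    pos_label=None,
) -> CVReport:
    """Pooled k-fold cross-validated ROC AUC over candidate model sizes.

    For each training fold, features are re-ranked by |CAT score| and the
    top-s features fitted for every candidate size s; out-of-fold
    posteriors are pooled across folds and the AUC computed once per size
    on the pooled scores (the pooled-CV ROC).  The returned report carries
    the size maximizing pooled AUC (smallest size on ties) and the feature
    set selected at that size on the full data.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    names = list(X.columns.astype(str))
    Xa = X.to_numpy(dtype=float)
    y = np.asarray(y)
    if pos_label is None:
        pos_label = np.unique(y)[0]
    if candidate_sizes is None:
        candidate_sizes = list(range(1, min(15, Xa.shape[1]) + 1))
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, k, rng)
    y01 = (y == pos_label).astype(int)

    post = {s: np.full(len(y), np.nan) for s in candidate_sizes}
    for fold in range(k):
        test = folds == fold
        if not test.any():
            continue
        train = ~test
        if np.unique(y[train]).size < 2:
            raise ValueError("a training fold lost one class; reduce k")
        order = _rank_features(Xa[train], y[train], names)
        for s in candidate_sizes:
            cols = order[:s]
            model = fit_slda(
                Xa[np.ix_(train, cols)], y[train],
                [names[c] for c in cols], pos_label=pos_label,
            )
            post[s][test] = model.posterior(Xa[np.ix_(test, cols)])

    auc_by_size = {
        s: float(roc_auc_score(y01, post[s])) for s in candidate_sizes
    }
    best_size = max(candidate_sizes, key=lambda s: (auc_by_size[s], -s))
    full_order = _rank_features(Xa, y, names)
    selected = [names[i] for i in full_order[:best_size]]
    return CVReport(
        k=k,
        seed=seed,
        fold_assignments=folds,
        candidate_sizes=list(candidate_sizes),
        auc_by_size=auc_by_size,
        best_size=best_size,
        posteriors=post[best_size],
        labels=y,
        auc=auc_by_size[best_size],
        selected_features=selected,
    )


def auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    pos_label=None,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified bootstrap percentile 95% CI for the ROC AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if pos_label is None:
        pos_label = np.unique(labels)[0]
    y01 = (labels == pos_label).astype(int)
    pos = np.flatnonzero(y01 == 1)
    neg = np.flatnonzero(y01 == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            bp = rng.choice(pos, size=len(pos), replace=True)
            bn = rng.choice(neg, size=len(neg), replace=True)
            sp, sn = scores[bp], scores[bn]
            if np.unique(np.concatenate([sp, sn])).size > 1:
                break
        greater = (sp[:, None] > sn[None, :]).sum()
        equal = (sp[:, None] == sn[None, :]).sum()
        aucs[b] = (greater + 0.5 * equal) / (len(bp) * len(bn))
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def youden_cutpoint(
    scores: np.ndarray, labels: np.ndarray, pos_label=None
) -> tuple[float, float]:
    """Threshold over observed scores maximizing J = sens + spec - 1.

    Prediction rule: positive iff score >= threshold.  On ties in J the
    smallest qualifying threshold is returned (deterministic).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if pos_label is None:
        pos_label = np.unique(labels)[0]
    y01 = labels == pos_label
    best_t, best_j = float("nan"), -np.inf
    for t in np.sort(np.unique(scores)):
        pred = scores >= t
        sens = (pred & y01).sum() / y01.sum()
        spec = (~pred & ~y01).sum() / (~y01).sum()
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    return best_t, float(best_j)


def repeated_cv_cutpoint(
    X: pd.DataFrame,
    y: np.ndarray,
    k: int = 10,
    candidate_sizes: list[int] | None = None,
    repeats: int = 50,
    seed: int = 0,
    pos_label=None,
) -> float:
    """Median over CV repeats of the per-repeat Youden-optimal threshold."""
    thresholds = []
    for r in range(repeats):
        rep = cv_pooled_roc(
            X, y, k=k, candidate_sizes=candidate_sizes,
            seed=seed + 1000 * (r + 1), pos_label=pos_label,
        )
        t, _ = youden_cutpoint(rep.posteriors, rep.labels, pos_label=pos_label)
        thresholds.append(t)
    return float(np.median(thresholds))


def diagnostic_odds_ratio(
    tp: int, fn: int, fp: int, tn: int
) -> tuple[float, tuple[float, float]]:
    """Diagnostic odds ratio with Woolf logit 95% CI.

    A Haldane-Anscombe 0.5 correction is applied to every cell whenever any
    cell is zero, keeping the OR and its CI finite.
    """
    cells = np.array([tp, fn, fp, tn], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be non-negative")
    if np.any(cells == 0):
        cells = cells + 0.5
    a, b, c, d = cells
    or_ = (a * d) / (c * b)
    se = np.sqrt((1 / cells).sum())
    lo = float(np.exp(np.log(or_) - 1.96 * se))
    hi = float(np.exp(np.log(or_) + 1.96 * se))
    return float(or_), (lo, hi)


def confusion_at(
    scores: np.ndarray, labels: np.ndarray, threshold: float, pos_label=None
) -> dict:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if pos_label is None:
        pos_label = np.unique(labels)[0]
    y01 = labels == pos_label
    pred = scores >= threshold
    return {
        "TP": int((pred & y01).sum()),
        "FN": int((~pred & y01).sum()),
        "FP": int((pred & ~y01).sum()),
        "TN": int((~pred & ~y01).sum()),
    }
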