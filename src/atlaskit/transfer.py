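"""Cell-type similarity assessment by penalized multinomial regression.

A ridge (L2) multinomial classifier is trained on a labelled reference with
10-fold cross-validation over a descending penalty grid; the penalty is
chosen by the one-standard-error rule (the largest penalty whose CV
deviance is within one SE of the minimum).  Query class probabilities are
averaged over 50 refits with reshuffled folds, and cluster-level calls are
made by the MAD-outlier test on per-cluster median probabilities: a query
cluster is significantly similar to a reference class when the BH-adjusted
p is below 0.05 *and* its median probability exceeds 50%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .qc import median_normalize, select_hvg
from .stats import bh_adjust, mad_outlier_upper

__all__ = [
    "RidgeModel",
    "SimilarityResult",
    "fit_cv_ridge",
    "transfer_probabilities",
    "call_similarity",
]

MIN_GENE_OVERLAP = 50


@dataclass
class RidgeModel:
    """Fitted CV-ridge multinomial model.

    ``coef`` is genes x classes (binary problems are expanded to two
    columns), intercepts are unpenalized.  The CV curve (mean held-out
    deviance per grid point and its standard error across folds) and the
    descending penalty grid are retained so the one-SE selection is
    auditable.
    """

    classes: np.ndarray
    coef: np.ndarray
    intercept: np.ndarray
    lambda_selected: float
    lambda_grid: np.ndarray
    cv_deviance: np.ndarray
    cv_deviance_se: np.ndarray

    def predict_proba(self, X) -> np.ndarray:
        """Softmax class probabilities for rows of ``X`` (cells x genes)."""
        X = np.asarray(X, dtype=float)
        scores = X @ self.coef + self.intercept
        scores -= scores.max(axis=1, keepdims=True)
        e = np.exp(scores)
        return e / e.sum(axis=1, keepdims=True)


def _lambda_grid(X: np.ndarray, y_codes: np.ndarray, n_classes: int,
                 n_lambda: int, n_decades: float = 4.0) -> np.ndarray:
    """Descending log-spaced penalty grid from a data-derived lambda_max.

    lambda_max follows the glmnet convention: the lasso bound
    ``max_j,c |x_j . (y_c - pi_c)| / N`` inflated by 1000, since no finite
    ridge penalty drives coefficients exactly to zero.
    """
    n = X.shape[0]
    Y = np.zeros((n, n_classes))
    Y[np.arange(n), y_codes] = 1.0
    prior = Y.mean(axis=0)
    grad = X.T @ (Y - prior)  # genes x classes
    lam_max = 1000.0 * np.abs(grad).max() / n
    lam_max = max(lam_max, 1e-6)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - n_decades, n_lambda)


def _expand_coef(est: LogisticRegression, n_classes: int) -> tuple[np.ndarray, np.ndarray]:
    coef = est.coef_
    intercept = est.intercept_
    if n_classes == 2 and coef.shape[0] == 1:
        coef = np.vstack([-coef[0] / 2, coef[0] / 2])
        intercept = np.array([-intercept[0] / 2, intercept[0] / 2])
    return coef.T, intercept


def _fit_path(X, y, lambdas, tol=1e-4):
    """Warm-started lbfgs fits along a descending penalty path."""
    n = X.shape[0]
    est = LogisticRegression(solver="lbfgs", warm_start=True,  # ridge (L2) penalty
                             max_iter=2000, tol=tol)
    for lam in lambdas:
        est.C = 1.0 / (n * lam)
        est.fit(X, y)
        yield est


def _deviance(est: LogisticRegression, X, y) -> float:
    p = est.predict_proba(X)
    idx = np.searchsorted(est.classes_, y)
    return float(-2.0 * np.mean(np.log(np.maximum(p[np.arange(len(y)), idx], 1e-300))))


def fit_cv_ridge(X, labels, n_folds: int = 10, n_lambda: int = 50,
                 seed: int = 0, n_decades: float = 4.0) -> RidgeModel:
    """Fit the multinomial ridge classifier with one-SE penalty selection.

    Minimizes ``(1/N) * multinomial NLL + (lambda/2) * ||coef||^2``
    (intercepts unpenalized) over a log-spaced grid spanning ``n_decades``
    decades below the data-derived lambda_max.  Stratified ``n_folds``-fold
    CV gives the mean held-out deviance and its SE per grid point; the
    selected penalty is the largest one within one SE of the minimum, and
    the model is refit on all data at that penalty.

    Parameters
    ----------
    X : (cells, genes) array
        Standardized expression (a warning is emitted if it does not look
        standardized).
    labels : array-like
        Per-cell class labels, >= 2 classes.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes, y_codes = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need >= 2 classes")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    nonconst = sd > 0
    if np.any(nonconst) and (np.any(np.abs(mu[nonconst]) > 0.1)
                             or np.any(np.abs(sd[nonconst] - 1.0) > 0.2)):
        warnings.warn("input does not look standardized (per-gene mean ~0, sd ~1 expected)")

    min_class = np.bincount(y_codes).min()
    folds = n_folds
    if min_class < n_folds:
        folds = max(int(min_class), 2)
        warnings.warn(f"smallest class has {min_class} cells; shrinking to {folds} folds")

    lambdas = _lambda_grid(X, y_codes, classes.size, n_lambda, n_decades)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.empty((folds, lambdas.size))
    for f, (tr, te) in enumerate(skf.split(X, y_codes)):
        for j, est in enumerate(_fit_path(X[tr], y_codes[tr], lambdas)):
            dev[f, j] = _deviance(est, X[te], y_codes[te])
    cvm = dev.mean(axis=0)
    cvse = dev.std(axis=0, ddof=1) / np.sqrt(folds)

    i_min = int(np.argmin(cvm))
    threshold = cvm[i_min] + cvse[i_min]
    i_sel = int(np.flatnonzero(cvm <= threshold)[0])  # grid descends: first = largest lambda
    lam_sel = float(lambdas[i_sel])

    final = LogisticRegression(solver="lbfgs", max_iter=5000,
                               tol=1e-6, C=1.0 / (X.shape[0] * lam_sel))
    final.fit(X, y_codes)
    coef, intercept = _expand_coef(final, classes.size)
    return RidgeModel(classes=classes, coef=coef, intercept=intercept,
                      lambda_selected=lam_sel, lambda_grid=lambdas,
                      cv_deviance=cvm, cv_deviance_se=cvse)


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    out = np.zeros_like(X)
    nz = sd > 0
    out[:, nz] = (X[:, nz] - mu[nz]) / sd[nz]
    return out


def transfer_probabilities(ref: AnnData, ref_labels, query: AnnData,
                           n_iter: int = 50, n_folds: int = 10, seed: int = 0,
                           features=None) -> pd.DataFrame:
    """Averaged reference-class probabilities for every query cell.

    The feature space is the reference's highly variable genes intersected
    with the query's genes (>= 50 required) on median-normalized log
    expression, standardized gene-wise *independently* within reference and
    query.  Each of ``n_iter`` iterations reshuffles the CV folds
    (``seed + i``), refits the CV-ridge model and predicts the query; the
    output is the element-wise mean, so rows still sum to 1.

    Parameters
    ----------
    ref : AnnData
        Reference counts.
    ref_labels : array-like or str
        Per-cell reference class labels, or the name of an ``obs`` column.
    query : AnnData
        Query counts (cells or spatial spots).
    features : sequence of str, optional
        Explicit feature space, bypassing HVG selection.
    """
    if isinstance(ref_labels, str):
        ref_labels = ref.obs[ref_labels].to_numpy()
    ref_labels = np.asarray(ref_labels)

    _, ref_log = median_normalize(ref)
    _, query_log = median_normalize(query)

    if features is None:
        features = select_hvg(ref_log, gene_names=list(ref.var_names))
    qset = set(query.var_names)
    common = [g for g in features if g in qset]
    if len(common) < MIN_GENE_OVERLAP:
        raise ValueError(
            f"only {len(common)} reference features overlap the query; "
            f"need >= {MIN_GENE_OVERLAP} ({MIN_GENE_OVERLAP - len(common)} short)")

    ref_idx = [ref.var_names.get_loc(g) for g in common]
    q_idx = [query.var_names.get_loc(g) for g in common]
    Xr = _standardize(ref_log[:, ref_idx])
    Xq = _standardize(query_log[:, q_idx])

    acc = None
    classes = None
    for i in range(n_iter):
        model = fit_cv_ridge(Xr, ref_labels, n_folds=n_folds, seed=seed + i)
        p = model.predict_proba(Xq)
        acc = p if acc is None else acc + p
        classes = model.classes
    proba = acc / n_iter
    return pd.DataFrame(proba, index=query.obs_names, columns=classes)


@dataclass
class SimilarityResult:
    """Averaged probabilities plus cluster-level significance calls."""

    probabilities: pd.DataFrame      # query cells x reference classes
    calls: pd.DataFrame              # tidy: query_cluster, ref_class, median_prob, robust_z, p, q, significant
    alpha: float
    min_prob: float

    def significant_pairs(self) -> set:
        sig = self.calls[self.calls["significant"]]
        return set(zip(sig["query_cluster"], sig["ref_class"]))


def call_similarity(probabilities: pd.DataFrame, query_clusters, alpha: float = 0.05,
                    min_prob: float = 0.5, joint_bh: bool = True) -> SimilarityResult:
    """Cluster-level significance calls on averaged transfer probabilities.

    For each reference class, the median probability per query cluster is
    computed and the MAD-outlier test run *across query clusters* (which
    clusters stand out for that label).  BH correction is applied jointly
    over all (cluster, class) pairs by default (``joint_bh=False`` adjusts
    within class).  Significance requires both q < ``alpha`` and a median
    probability above ``min_prob``.
    """
    query_clusters = np.asarray(query_clusters)
    if query_clusters.size != probabilities.shape[0]:
        raise ValueError("query_clusters length must match probability rows")
    uniq = pd.unique(query_clusters)
    if uniq.size < 2:
        raise ValueError("cluster-level outlier test needs >= 2 query clusters")

    medians = probabilities.groupby(query_clusters, sort=True).median()
    rows = []
    for ref_class in probabilities.columns:
        res = mad_outlier_upper(medians[ref_class].to_numpy(), alpha=alpha)
        for i, cl in enumerate(medians.index):
            rows.append({
                "query_cluster": cl, "ref_class": ref_class,
                "median_prob": medians.at[cl, ref_class],
                "robust_z": res.robust_z[i], "p": res.p[i],
            })
    calls = pd.DataFrame(rows)
    if joint_bh:
        calls["q"] = bh_adjust(calls["p"].to_numpy())
    else:
        calls["q"] = calls.groupby("ref_class")["p"].transform(lambda s: bh_adjust(s.to_numpy()))
    calls["significant"] = (calls["q"] < alpha) & (calls["median_prob"] > min_prob)
    return SimilarityResult(probabilities=probabilities, calls=calls,
                            alpha=alpha, min_prob=min_prob)
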