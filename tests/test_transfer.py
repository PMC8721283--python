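"""Ridge label transfer: CV penalty selection, probability averaging and
cluster-level significance calling."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from atlaskit import (AtlasConfig, call_similarity, fit_cv_ridge, simulate_atlas,
                      transfer_probabilities)
from atlaskit.transfer import _fit_path, _standardize


def _separated_clusters(rng, n_per=100, n_genes=20, n_classes=3, sep=3.0):
    X = rng.normal(size=(n_per * n_classes, n_genes))
    for c in range(n_classes):
        X[c * n_per:(c + 1) * n_per, c] += sep
    labels = np.repeat([f"k{c}" for c in range(n_classes)], n_per)
    return _standardize(X), labels


@pytest.fixture(scope="module")
def small_atlas():
    return simulate_atlas(AtlasConfig(n_clusters=3, cells_per_cluster=60,
                                      n_genes=300, markers_per_cluster=20, seed=11))


def _ridge_objective(W, b, X, y_codes, lam, K):
    scores = X @ W + b
    scores -= scores.max(axis=1, keepdims=True)
    logp = scores - np.log(np.exp(scores).sum(axis=1, keepdims=True))
    nll = -logp[np.arange(len(y_codes)), y_codes].mean()
    return nll + 0.5 * lam * np.sum(W * W)


def test_fit_cv_ridge_one_se_rule_and_accuracy(rng):
    X, labels = _separated_clusters(rng)
    model = fit_cv_ridge(X, labels, seed=0)
    # one-SE: selected penalty at least as strong as the deviance minimizer
    lam_min = model.lambda_grid[np.argmin(model.cv_deviance)]
    assert model.lambda_selected >= lam_min
    pred = model.classes[model.predict_proba(X).argmax(axis=1)]
    assert (pred == labels).mean() >= 0.95


def test_fit_cv_ridge_matches_convex_optimizer_oracle(rng):
    # same objective minimized by a generic optimizer from scratch
    X, labels = _separated_clusters(rng, n_per=60)
    model = fit_cv_ridge(X, labels, seed=1)
    classes, y_codes = np.unique(labels, return_inverse=True)
    K, G = classes.size, X.shape[1]
    lam = model.lambda_selected

    def fun(theta):
        W = theta[: G * K].reshape(G, K)
        b = theta[G * K:]
        return _ridge_objective(W, b, X, y_codes, lam, K)

    res = minimize(fun, np.zeros(G * K + K), method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-12})
    ours = _ridge_objective(model.coef, model.intercept, X, y_codes, lam, K)
    assert ours == pytest.approx(res.fun, rel=1e-3, abs=1e-4)
    # and the probabilities agree where it matters
    W = res.x[: G * K].reshape(G, K)
    b = res.x[G * K:]
    s = X @ W + b
    p_oracle = np.exp(s - s.max(1, keepdims=True))
    p_oracle /= p_oracle.sum(1, keepdims=True)
    assert np.abs(model.predict_proba(X) - p_oracle).max() < 0.02


def test_infinite_penalty_limit_recovers_priors(rng):
    X, labels = _separated_clusters(rng)
    # unbalance the classes so the prior limit is informative
    keep = np.r_[np.arange(100), np.arange(100, 150), np.arange(200, 225)]
    X, labels = X[keep], labels[keep]
    model = fit_cv_ridge(X, labels, seed=0)
    est = list(_fit_path(X, np.searchsorted(np.unique(labels), labels),
                         [model.lambda_grid[0]]))[0]
    priors = np.bincount(np.searchsorted(np.unique(labels), labels)) / len(labels)
    assert np.abs(est.predict_proba(X) - priors).max() < 0.05


def test_fit_cv_ridge_single_class_errors():
    with pytest.raises(ValueError):
        fit_cv_ridge(np.random.default_rng(0).normal(size=(20, 5)), ["a"] * 20)


def test_fit_cv_ridge_warns_on_unstandardized(rng):
    X = rng.normal(loc=5.0, size=(40, 5))
    with pytest.warns(UserWarning, match="standardized"):
        fit_cv_ridge(X, np.repeat(["a", "b"], 20), n_folds=3, seed=0)


# ---------------------------------------------------------------------------
# transfer_probabilities

def test_self_transfer_rows_and_accuracy(default_atlas):
    proba = transfer_probabilities(default_atlas, "cluster", default_atlas,
                                   n_iter=2, seed=0)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-8)
    acc = (proba.idxmax(axis=1).to_numpy() == default_atlas.obs["cluster"].to_numpy()).mean()
    assert acc >= 0.95


def test_fresh_query_cluster_mapping(small_atlas):
    # query from the same generative model (same gene-mean landscape and
    # marker layout) with fresh sampling noise
    cfg = AtlasConfig(n_clusters=3, cells_per_cluster=60, n_genes=300,
                      markers_per_cluster=20, seed=12, structure_seed=11)
    query = simulate_atlas(cfg)
    proba = transfer_probabilities(small_atlas, "cluster", query, n_iter=2, seed=0)
    medians = proba.groupby(query.obs["cluster"].to_numpy()).median()
    mapping = medians.idxmax(axis=1)
    # the real (generative) clusters must map to themselves; the doublet
    # pseudo-cluster holds random parent mixtures and is not a fixed class
    real = [c for c in medians.index if c != "doublet"]
    assert all(mapping[c] == c for c in real)


def test_duplicated_reference_cluster_symmetry(default_atlas):
    # splitting one reference cluster into two identical halves: cells of
    # that type divide their probability between the duplicates, and the
    # median probabilities (the quantity the significance call uses) agree
    labels = default_atlas.obs["cluster"].to_numpy().copy()
    c0 = np.flatnonzero(labels == "cluster_0")
    labels[c0[::2]] = "cluster_0b"
    proba = transfer_probabilities(default_atlas, labels, default_atlas, n_iter=2, seed=0)
    true_c0 = default_atlas.obs["true_cluster"].to_numpy() == "cluster_0"
    med_a = proba.loc[true_c0, "cluster_0"].median()
    med_b = proba.loc[true_c0, "cluster_0b"].median()
    assert abs(med_a - med_b) < 0.15
    # and jointly they still own those cells
    assert (proba.loc[true_c0, ["cluster_0", "cluster_0b"]].sum(axis=1)).median() > 0.8


def test_transfer_deterministic_given_seed(small_atlas):
    p1 = transfer_probabilities(small_atlas, "cluster", small_atlas, n_iter=2, seed=3)
    p2 = transfer_probabilities(small_atlas, "cluster", small_atlas, n_iter=2, seed=3)
    np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-10)


def test_constant_gene_is_removed_by_standardization(rng, small_atlas):
    # exact at the fit level: a zero-variance gene standardizes to an
    # all-zero column, which keeps a zero coefficient throughout
    X, labels = _separated_clusters(rng)
    model = fit_cv_ridge(X, labels, seed=0)
    X_aug = np.column_stack([X, np.zeros(X.shape[0])])
    model_aug = fit_cv_ridge(X_aug, labels, seed=0)
    np.testing.assert_allclose(model_aug.coef[-1], 0.0, atol=1e-12)
    np.testing.assert_allclose(model_aug.predict_proba(X_aug),
                               model.predict_proba(X), atol=1e-8)
    # end to end, a constant-count gene leaves cell assignments essentially
    # unchanged (it only perturbs the normalization totals)
    from anndata import AnnData
    from scipy import sparse
    base = transfer_probabilities(small_atlas, "cluster", small_atlas, n_iter=1, seed=0)
    Xc = np.asarray(small_atlas.X.todense())
    X2 = np.column_stack([Xc, np.full(Xc.shape[0], 5.0)])
    var = pd.DataFrame(index=list(small_atlas.var_names) + ["SHIFT"])
    aug = AnnData(X=sparse.csr_matrix(X2), obs=small_atlas.obs.copy(), var=var)
    shifted = transfer_probabilities(aug, "cluster", aug, n_iter=1, seed=0)
    agree = (base.idxmax(axis=1).to_numpy() == shifted.idxmax(axis=1).to_numpy()).mean()
    assert agree >= 0.98


def test_transfer_insufficient_overlap_errors(small_atlas):
    from anndata import AnnData
    query = AnnData(X=np.ones((10, 30)),
                    var=pd.DataFrame(index=[f"OTHER{j}" for j in range(30)]))
    with pytest.raises(ValueError, match="overlap"):
        transfer_probabilities(small_atlas, "cluster", query, n_iter=1)


# ---------------------------------------------------------------------------
# call_similarity

def test_uniform_probabilities_nothing_significant(rng):
    K = 4
    proba = pd.DataFrame(np.full((80, K), 1.0 / K), columns=[f"r{k}" for k in range(K)])
    res = call_similarity(proba, np.repeat([f"q{k}" for k in range(4)], 20))
    assert not res.calls["significant"].any()


def test_planted_high_median_cluster_significant(rng):
    # one query cluster with median 0.9 for class C, all others at 0.05
    n_clusters, n_per = 6, 15
    pc = np.full((n_clusters * n_per, 3), 0.05)
    pc[:n_per, 0] = 0.9
    pc = pc / pc.sum(axis=1, keepdims=True) * 1.0
    # rebuild so rows sum to one but medians stay at the planted levels
    proba = pd.DataFrame(np.column_stack([pc[:, 0], (1 - pc[:, 0]) / 2, (1 - pc[:, 0]) / 2]),
                         columns=["C", "D", "E"])
    clusters = np.repeat([f"q{k}" for k in range(n_clusters)], n_per)
    res = call_similarity(proba, clusters, alpha=0.05)
    sig = res.significant_pairs()
    assert ("q0", "C") in sig
    assert all(pair[1] != "C" or pair[0] == "q0" for pair in sig)


def test_call_similarity_single_cluster_errors():
    proba = pd.DataFrame(np.full((10, 2), 0.5), columns=["a", "b"])
    with pytest.raises(ValueError):
        call_similarity(proba, ["only"] * 10)
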