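"""Shared statistical primitives.

Robust-outlier significance calling (median/MAD z-scores referred to a
Student-t), Benjamini-Hochberg step-up correction, rank-based two-sample
tests and one-vs-rest marker-gene testing.  These are the building blocks
the higher-level stages (doublet flagging, label-transfer significance,
gene-set comparisons) delegate to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "OutlierTestResult",
    "bh_adjust",
    "mad_outlier_upper",
    "mann_whitney",
    "kruskal_wallis",
    "pearson",
    "marker_genes",
]

#: floor added to the scaled MAD so exact-centre values keep p = 0.5 and any
#: strictly larger value becomes an extreme outlier when the MAD is zero.
MAD_EPS = 1e-9

#: normal-consistency factor for the MAD.
MAD_SCALE = 1.4826


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorts ascending, takes ``adj_(i) = min_{j >= i} p_(j) * m / j`` clipped to
    [0, 1], and returns the adjusted values in the original order.

    Parameters
    ----------
    p_values : array-like of float
        Raw p-values, each in [0, 1].

    Returns
    -------
    numpy.ndarray
        Adjusted values, same order as the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass(frozen=True)
class OutlierTestResult:
    """Per-item result of the one-tailed MAD-outlier test.

    Attributes
    ----------
    robust_z : numpy.ndarray
        ``(v_i - median(v)) / (1.4826 * MAD(v) + eps)``.
    p : numpy.ndarray
        One-tailed upper-tail p-values.
    q : numpy.ndarray
        BH-adjusted p-values.
    flagged : numpy.ndarray of bool
        ``q < alpha``.
    alpha : float
        Significance level used for flagging.
    """

    robust_z: np.ndarray
    p: np.ndarray
    q: np.ndarray
    flagged: np.ndarray
    alpha: float


def mad_outlier_upper(values, alpha: float = 0.05, reference: str = "t") -> OutlierTestResult:
    """One-tailed upper MAD-outlier test with BH correction.

    Each value is converted to a robust z-score around the median, scaled by
    the normal-consistent MAD (with a tiny floor so a zero MAD does not
    divide by zero: values at the centre get p = 0.5 and anything strictly
    larger is an extreme outlier).  The robust z is referred to a Student-t
    with ``n - 1`` degrees of freedom (upper tail), or to a standard normal
    when ``reference="normal"``.

    Parameters
    ----------
    values : array-like of float
        At least two finite values.
    alpha : float
        Flagging level applied to the BH-adjusted p-values.
    reference : {"t", "normal"}
        Null reference distribution for the robust z.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("mad_outlier_upper needs at least 2 values")
    if np.any(~np.isfinite(v)):
        raise ValueError("values must be finite")
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    z = (v - med) / (MAD_SCALE * mad + MAD_EPS)
    if reference == "t":
        p = sps.t.sf(z, df=v.size - 1)
    elif reference == "normal":
        p = sps.norm.sf(z)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    q = bh_adjust(p)
    return OutlierTestResult(robust_z=z, p=p, q=q, flagged=q < alpha, alpha=alpha)


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _exact_mw_p(a: np.ndarray, b: np.ndarray, u_a: float, alternative: str) -> float:
    """Exact Mann-Whitney p by enumerating group assignments of the pooled
    midranks.  Valid with ties (the midrank pattern is held fixed)."""
    na, nb = a.size, b.size
    ranks = _midranks(np.concatenate([a, b]))
    n = na + nb
    total = comb(n, na)
    offset = na * (na + 1) / 2.0
    us = np.empty(total)
    for i, idx in enumerate(combinations(range(n), na)):
        us[i] = ranks[list(idx)].sum() - offset
    mu = na * nb / 2.0
    tol = 1e-9
    if alternative == "greater":
        count = np.sum(us >= u_a - tol)
    elif alternative == "less":
        count = np.sum(us <= u_a + tol)
    else:
        count = np.sum(np.abs(us - mu) >= abs(u_a - mu) - tol)
    return float(count) / total


def mann_whitney(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test with midrank ties.

    Returns ``(U_a, p)`` where ``U_a`` is the U statistic of the first
    sample.  The p-value comes from exact enumeration of all group
    assignments when ``len(a) + len(b) <= 10``, otherwise from the normal
    approximation with tie and continuity corrections.

    Parameters
    ----------
    a, b : array-like of float
        The two samples; both must be non-empty.
    alternative : {"two-sided", "greater", "less"}
        ``"greater"`` means the first sample tends larger.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    ranks = _midranks(np.concatenate([a, b]))
    u_a = float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)
    if a.size + b.size <= 10:
        p = _exact_mw_p(a, b, u_a, alternative)
    else:
        res = sps.mannwhitneyu(a, b, alternative=alternative, method="asymptotic",
                               use_continuity=True)
        p = float(res.pvalue)
    return u_a, min(p, 1.0)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H test over a sequence of samples (thin scipy wrapper)."""
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def pearson(x, y) -> float:
    """Sample Pearson correlation; NaN when either vector is constant."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc * xc))
    sy = np.sqrt(np.sum(yc * yc))
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.dot(xc, yc) / (sx * sy))


def marker_genes(norm_expr, labels, gene_names=None) -> pd.DataFrame:
    """One-vs-rest rank-sum marker test per cluster.

    For every cluster, each gene is tested cluster-vs-rest with the
    Mann-Whitney U test (normal approximation with tie correction — the
    standard choice at single-cell sample sizes), BH-corrected within the
    cluster.  The fold change is ``log2((mean_in + 1) / (mean_out + 1))`` on
    the supplied normalized expression.

    Parameters
    ----------
    norm_expr : (cells, genes) array-like
        Normalized expression (dense or sparse).
    labels : array-like
        Per-cell cluster labels, >= 2 distinct.
    gene_names : sequence of str, optional
        Column names; defaults to ``g0..g{n-1}``.

    Returns
    -------
    pandas.DataFrame
        Tidy table with columns ``cluster, gene, log2_fc, p, q``.
    """
    X = norm_expr
    if hasattr(X, "toarray"):
        X = X.toarray()
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.shape[0] != labels.size:
        raise ValueError("labels length must match number of rows")
    uniq = pd.unique(labels)
    if uniq.size < 2:
        raise ValueError("need >= 2 clusters")
    if gene_names is None:
        gene_names = [f"g{j}" for j in range(X.shape[1])]
    gene_names = np.asarray(gene_names)

    rows = []
    for cl in uniq:
        mask = labels == cl
        if mask.sum() < 2:
            warnings.warn(f"cluster {cl!r} has < 2 cells; skipped")
            continue
        a = X[mask]
        b = X[~mask]
        with np.errstate(invalid="ignore"):
            res = sps.mannwhitneyu(a, b, axis=0, alternative="two-sided",
                                   method="asymptotic", use_continuity=True)
        p = np.asarray(res.pvalue, dtype=float)
        # constant genes: U at its null mean with zero variance -> no evidence
        const = X.max(axis=0) == X.min(axis=0)
        p[const | ~np.isfinite(p)] = 1.0
        lfc = np.log2((a.mean(axis=0) + 1.0) / (b.mean(axis=0) + 1.0))
        q = bh_adjust(p)
        rows.append(pd.DataFrame({
            "cluster": cl, "gene": gene_names, "log2_fc": lfc, "p": p, "q": q,
        }))
    return pd.concat(rows, ignore_index=True)
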