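"""Bulk deconvolution and survival stratification.

Per-sample cell-type proportions are estimated by (optionally gene-
weighted) non-negative least squares against single-cell reference
signatures, samples are stratified into the top and bottom quartiles of a
chosen cell type's score, and the groups are compared with the
Kaplan-Meier product-limit estimator and the two-group log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import nnls

__all__ = [
    "DeconvResult",
    "SurvivalFit",
    "build_signatures",
    "nnls_deconvolve",
    "stratify_quartiles",
    "km_estimate",
    "logrank_test",
]


def build_signatures(ref, labels, scale: str = "linear") -> pd.DataFrame:
    """Per-class mean reference profiles (genes x classes) for deconvolution.

    Cells are median-normalized first so library size does not weight the
    profile; ``scale`` selects linear (default) or ``"log"`` (log1p) means.
    ``ref`` is an AnnData; ``labels`` an array or ``obs`` column name.
    """
    from .qc import median_normalize

    if isinstance(labels, str):
        labels = ref.obs[labels].to_numpy()
    labels = np.asarray(labels)
    norm, log_norm = median_normalize(ref)
    X = norm if scale == "linear" else log_norm
    if scale not in ("linear", "log"):
        raise ValueError("scale must be 'linear' or 'log'")
    cols = {}
    for cl in pd.unique(labels):
        cols[cl] = X[labels == cl].mean(axis=0)
    return pd.DataFrame(cols, index=ref.var_names)


@dataclass
class DeconvResult:
    """NNLS deconvolution output.

    ``proportions`` rows are non-negative and sum to 1; samples whose NNLS
    solution is all-zero get NaN proportions and appear in
    ``undefined_samples``.
    """

    proportions: pd.DataFrame   # samples x classes
    residual_norm: pd.Series    # per-sample ||S x - b||
    undefined_samples: list


def nnls_deconvolve(bulk: pd.DataFrame, signatures: pd.DataFrame,
                    weights=None) -> DeconvResult:
    """Estimate cell-type proportions of bulk samples by NNLS.

    Solves ``min_x ||W^(1/2) (S x - b)||^2, x >= 0`` per sample over the
    shared gene space and normalizes ``x`` to the unit simplex.

    Parameters
    ----------
    bulk : pandas.DataFrame
        Samples x genes expression.
    signatures : pandas.DataFrame
        Genes x classes mean reference profiles (e.g. per-class means of
        median-normalized linear expression).
    weights : array-like, optional
        Per-gene non-negative weights over the shared gene space (aligned
        to ``signatures``' gene order after intersection).
    """
    shared = [g for g in signatures.index if g in set(bulk.columns)]
    if not shared:
        raise ValueError("no shared genes between bulk and signatures")
    if signatures.shape[1] < 2:
        raise ValueError("need >= 2 reference classes")
    S = signatures.loc[shared].to_numpy(dtype=float)
    B = bulk[shared].to_numpy(dtype=float)
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        if w.size != len(shared) or np.any(w < 0):
            raise ValueError("weights must be non-negative, one per shared gene")
        S = S * w[:, None]
        B = B * w[None, :]

    props = np.empty((B.shape[0], S.shape[1]))
    resid = np.empty(B.shape[0])
    undefined = []
    for i in range(B.shape[0]):
        x, r = nnls(S, B[i])
        resid[i] = r
        tot = x.sum()
        if tot <= 0:
            props[i] = np.nan
            undefined.append(bulk.index[i])
        else:
            props[i] = x / tot
    return DeconvResult(
        proportions=pd.DataFrame(props, index=bulk.index, columns=signatures.columns),
        residual_norm=pd.Series(resid, index=bulk.index, name="residual_norm"),
        undefined_samples=undefined,
    )


def stratify_quartiles(scores) -> pd.Series:
    """Top/bottom-quartile stratification of per-sample scores.

    ``high`` = score >= 75th percentile, ``low`` = score <= 25th percentile
    (linear-interpolation quantiles, boundaries inclusive), everything else
    ``excluded``.
    """
    s = pd.Series(scores, dtype=float)
    if s.size < 4:
        raise ValueError("need >= 4 samples for quartile stratification")
    if s.nunique() == 1:
        raise ValueError("all scores identical; quartile groups undefined")
    q25, q75 = np.quantile(s.to_numpy(), [0.25, 0.75])
    if q25 == q75:
        raise ValueError("degenerate quartile boundaries; groups undefined")
    out = pd.Series("excluded", index=s.index, name="group", dtype=object)
    out[s >= q75] = "high"
    out[s <= q25] = "low"
    return out


@dataclass
class SurvivalFit:
    """Kaplan-Meier curves per group, plus the log-rank test when run on
    exactly two groups."""

    curves: dict                 # group -> DataFrame(time, n_at_risk, n_events, survival)
    logrank_statistic: float = float("nan")
    logrank_p: float = float("nan")


def _km_single(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])
    rows = []
    surv = 1.0
    for t in event_times:
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        surv *= 1.0 - d / n_at_risk
        rows.append({"time": t, "n_at_risk": n_at_risk, "n_events": d, "survival": surv})
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def km_estimate(times, events, groups=None) -> SurvivalFit:
    """Kaplan-Meier product-limit estimator per group.

    ``S(t) = prod_{t_i <= t} (1 - d_i / n_i)`` over distinct event times;
    censored subjects leave the risk set after their time.  ``groups`` of
    None fits a single curve named ``"all"``.
    """
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events).astype(int).ravel()
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if groups is None:
        groups = np.full(times.size, "all")
    groups = np.asarray(groups)
    curves = {}
    for g in pd.unique(groups):
        m = groups == g
        curves[g] = _km_single(times[m], events[m])
    return SurvivalFit(curves=curves)


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test.

    At each distinct event time the observed event count in group 1 is
    compared with its hypergeometric expectation given the risk sets;
    ``chi2 = (sum(O - E))^2 / sum(V)`` is referred to chi-square with 1 df.
    """
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events).astype(int).ravel()
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if labels.size != 2:
        raise ValueError("log-rank test requires exactly two groups")
    g1 = groups == labels[0]
    if g1.sum() == 0 or (~g1).sum() == 0:
        raise ValueError("both groups must be non-empty")

    event_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = int(np.sum((times == t) & (events == 1)))
        d1 = int(np.sum((times == t) & (events == 1) & g1))
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(sps.chi2.sf(chi2, df=1))
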