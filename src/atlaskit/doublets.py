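"""Cluster-level doublet flagging.

Doublets tend to land in small hybrid clusters with elevated per-cell
doublet scores.  Rather than thresholding individual cells, the test asks
whether a whole cluster's median doublet score is an upper outlier among
cluster medians: robust z against the median/MAD of the medians, one-tailed
t reference, BH correction, flag at q < 0.1.  The operation accepts any
supplied clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import mad_outlier_upper

__all__ = ["DoubletCallTable", "flag_doublet_clusters"]


@dataclass
class DoubletCallTable:
    """Cluster-level calls plus the per-cell flags they propagate to."""

    clusters: pd.DataFrame   # index: cluster; columns: median_score, robust_z, p, q, flagged
    cell_flags: pd.Series    # per-cell bool, inherited from the cell's cluster
    alpha: float


def flag_doublet_clusters(scores, clusters, alpha: float = 0.1) -> DoubletCallTable:
    """Flag clusters whose median doublet score is an upper MAD-outlier.

    Parameters
    ----------
    scores : array-like of float
        Per-cell doublet scores in [0, 1].
    clusters : array-like
        Per-cell cluster labels; >= 2 distinct clusters required.
    alpha : float
        BH-adjusted significance level for flagging.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    clusters = np.asarray(clusters)
    if scores.size != clusters.size:
        raise ValueError("scores and clusters must have equal length")
    if np.any(~np.isfinite(scores)):
        raise ValueError("scores must be finite")
    ser = pd.Series(scores, index=pd.Index(clusters, name="cluster"))
    medians = ser.groupby(level=0, sort=True).median()
    if medians.size < 2:
        raise ValueError("cluster-level outlier test needs >= 2 clusters")

    res = mad_outlier_upper(medians.to_numpy(), alpha=alpha)
    table = pd.DataFrame({
        "median_score": medians.to_numpy(),
        "robust_z": res.robust_z,
        "p": res.p,
        "q": res.q,
        "flagged": res.flagged,
    }, index=medians.index)
    cell_flags = pd.Series(table["flagged"].reindex(clusters).to_numpy(),
                           index=pd.RangeIndex(scores.size), name="doublet_flag")
    return DoubletCallTable(clusters=table, cell_flags=cell_flags, alpha=alpha)
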