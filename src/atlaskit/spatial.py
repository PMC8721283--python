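"""Spatial colocalization: spot-level cell-type scores and the
kNN-neighborhood Pearson statistic.

Each spot's neighborhood is itself plus its k nearest neighbors by
Euclidean distance (k + 1 values; ties broken by spot index).  Within each
neighborhood, Pearson correlation is computed between a per-spot feature
(a gene's expression or a two-gene module score) and a per-spot cell-type
score.  Neighborhoods where the feature is all-zero or either vector is
constant are excluded; the statistic is the mean over the rest.  A feature
uniform across all spots yields a missing result.  The per-spot map keeps
only positive values — a plotting convention that never touches the
returned mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy.spatial.distance import cdist

from .scoring import GeneSet, module_score
from .transfer import transfer_probabilities

__all__ = [
    "ColocResult",
    "predict_spot_types",
    "neighborhood_correlation",
    "two_gene_module",
]


def predict_spot_types(ref: AnnData, ref_labels, spatial: AnnData,
                       n_iter: int = 10, seed: int = 0) -> pd.DataFrame:
    """Probabilistic cell-type scores per spot via ridge label transfer.

    Applies :func:`atlaskit.transfer.transfer_probabilities` with spots as
    query cells; rows sum to 1.  The result is also stored in
    ``spatial.obsm["prediction"]``.
    """
    proba = transfer_probabilities(ref, ref_labels, spatial, n_iter=n_iter, seed=seed)
    spatial.obsm["prediction"] = proba.to_numpy()
    spatial.uns["prediction_classes"] = list(proba.columns)
    return proba


@dataclass
class ColocResult:
    """Result of the neighborhood-correlation statistic.

    ``mean_correlation`` is NaN when no usable neighborhood remains.
    ``per_spot`` holds every neighborhood's correlation (NaN where
    excluded); ``per_spot_positive`` masks negatives for plotting.
    """

    mean_correlation: float
    n_neighborhoods_used: int
    n_neighborhoods_excluded: int
    per_spot: np.ndarray
    per_spot_positive: np.ndarray


def _knn_indices(coords: np.ndarray, k: int) -> np.ndarray:
    """Indices of each spot's neighborhood: itself + k nearest (ties by index)."""
    d = cdist(coords, coords)
    np.fill_diagonal(d, -1.0)  # focal spot always first
    order = np.argsort(d, axis=1, kind="stable")  # stable => ties break by index
    return order[:, : k + 1]


def neighborhood_correlation(coords, feature, class_scores, k: int = 5) -> ColocResult:
    """Mean Pearson correlation of a feature with a cell-type score over
    kNN neighborhoods.

    Parameters
    ----------
    coords : (spots, 2) array or AnnData
        Spot coordinates (an AnnData uses ``.obsm["spatial"]``).
    feature : array-like of float
        Per-spot feature values (gene expression or module score).
    class_scores : array-like of float
        Per-spot cell-type prediction scores.
    k : int
        Number of neighbors; each neighborhood has k + 1 spots.
    """
    if isinstance(coords, AnnData):
        coords = coords.obsm["spatial"]
    coords = np.asarray(coords, dtype=float)
    feature = np.asarray(feature, dtype=float).ravel()
    class_scores = np.asarray(class_scores, dtype=float).ravel()
    n = coords.shape[0]
    if feature.size != n or class_scores.size != n:
        raise ValueError("feature and class_scores must have one value per spot")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of spots ({n})")

    per_spot = np.full(n, np.nan)
    if np.all(feature == feature[0]):
        # feature uniform across all spots: statistic undefined
        return ColocResult(float("nan"), 0, n, per_spot, per_spot.copy())

    nb = _knn_indices(coords, k)
    f = feature[nb]            # n x (k+1)
    c = class_scores[nb]
    all_zero = np.all(f == 0, axis=1)
    f_const = np.all(f == f[:, :1], axis=1)
    c_const = np.all(c == c[:, :1], axis=1)
    ok = ~(all_zero | f_const | c_const)

    fc = f - f.mean(axis=1, keepdims=True)
    cc = c - c.mean(axis=1, keepdims=True)
    num = (fc * cc).sum(axis=1)
    den = np.sqrt((fc * fc).sum(axis=1) * (cc * cc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    per_spot[ok] = r[ok]

    used = int(ok.sum())
    mean = float(np.nanmean(per_spot)) if used else float("nan")
    pos = np.where(per_spot > 0, per_spot, np.nan)
    return ColocResult(mean_correlation=mean, n_neighborhoods_used=used,
                       n_neighborhoods_excluded=n - used,
                       per_spot=per_spot, per_spot_positive=pos)


def two_gene_module(spot_log_norm, gene_names, genes: tuple, seed: int = 0,
                    **kwargs) -> np.ndarray:
    """Module score of a two-gene set on spot expression.

    ``spot_log_norm`` may be an AnnData (gene names taken from it when
    ``gene_names`` is None) or a matrix plus explicit names.
    """
    if isinstance(spot_log_norm, AnnData):
        if gene_names is None:
            gene_names = list(spot_log_norm.var_names)
        spot_log_norm = spot_log_norm.X
    g1, g2 = genes
    for g in (g1, g2):
        if g not in set(gene_names):
            raise ValueError(f"gene {g!r} not present in the spot matrix")
    return module_score(spot_log_norm, gene_names, GeneSet(f"{g1}+{g2}", (g1, g2)),
                        seed=seed, **kwargs)
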