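"""Quality-control filtering, median-total normalization and HVG selection.

The filter thresholds mirror the standard droplet-data recipe: cells are
kept with 200-2500 detected genes and a mitochondrial count share strictly
below 30%; genes must be expressed in at least 3 retained cells.  Filters
are iterated to a fixpoint so the returned matrix itself satisfies every
threshold and filtering is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

__all__ = ["QCReport", "qc_filter", "median_normalize", "select_hvg"]


@dataclass
class QCReport:
    """Bookkeeping of a QC pass.

    Cell removals are deduplicated by reason priority (gene-count bounds
    first, then the mito filter among the survivors), so
    ``n_cells_in - (high + low + mito) == n_cells_out``.
    """

    n_cells_in: int = 0
    n_cells_removed_genes_high: int = 0
    n_cells_removed_genes_low: int = 0
    n_cells_removed_mito: int = 0
    n_genes_removed: int = 0
    n_cells_out: int = 0
    n_genes_in: int = 0
    n_genes_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: [v] for k, v in self.__dict__.items()})


def _densify(X):
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)


def qc_filter(counts: AnnData, min_genes: int = 200, max_genes: int = 2500,
              max_mito_frac: float = 0.30, min_cells_per_gene: int = 3,
              mito_prefix: str = "MT-") -> tuple[AnnData, QCReport]:
    """Filter cells and genes by the standard droplet-QC thresholds.

    Cells with fewer than ``min_genes`` or more than ``max_genes`` detected
    genes (count > 0) are removed; of the remainder, cells whose
    mitochondrial count share is >= ``max_mito_frac`` are removed (the
    boundary fails: "< 30%" passes).  Genes expressed in fewer than
    ``min_cells_per_gene`` retained cells are then dropped.  The cell/gene
    round is repeated until stable, so the output matrix satisfies all
    thresholds simultaneously and the operation is idempotent.

    Returns the filtered copy and a :class:`QCReport` with deduplicated
    removal counts accumulated over rounds.  An empty result is returned as
    a zero-cell/zero-gene AnnData, not an error.
    """
    adata = counts.copy()
    report = QCReport(n_cells_in=adata.n_obs, n_genes_in=adata.n_vars)
    mito_mask_full = np.array([g.startswith(mito_prefix) for g in adata.var_names])

    while True:
        X = _densify(adata.X)
        mito = mito_mask_full
        detected = (X > 0).sum(axis=1)
        low = detected < min_genes
        high = detected > max_genes
        totals = X.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_share = np.where(totals > 0, X[:, mito].sum(axis=1) / np.maximum(totals, 1e-300), 0.0)
        mito_fail = (~low) & (~high) & (mito_share >= max_mito_frac)
        keep_cells = ~(low | high | mito_fail)

        report.n_cells_removed_genes_low += int(low.sum())
        report.n_cells_removed_genes_high += int(high.sum())
        report.n_cells_removed_mito += int(mito_fail.sum())

        Xc = X[keep_cells]
        prevalence = (Xc > 0).sum(axis=0)
        keep_genes = prevalence >= min_cells_per_gene
        report.n_genes_removed += int((~keep_genes).sum())

        changed = (not keep_cells.all()) or (not keep_genes.all())
        adata = adata[keep_cells, keep_genes].copy()
        mito_mask_full = mito_mask_full[keep_genes]
        if not changed or adata.n_obs == 0 or adata.n_vars == 0:
            break

    report.n_cells_out = adata.n_obs
    report.n_genes_out = adata.n_vars
    return adata, report


def median_normalize(counts) -> tuple[np.ndarray, np.ndarray]:
    """Scale each cell so its total equals the median of the input totals.

    Accepts an AnnData, a sparse matrix or a dense array (cells x genes).
    Returns ``(normalized, log1p(normalized))`` as dense arrays.  Raises if
    any cell has zero total (run QC first).
    """
    X = counts.X if isinstance(counts, AnnData) else counts
    X = _densify(X).astype(float)
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("cells with zero total counts present; apply qc_filter first")
    target = np.median(totals)
    norm = X * (target / totals)[:, None]
    return norm, np.log1p(norm)


def select_hvg(log_norm, gene_names=None, min_mean: float = 0.0125,
               max_mean: float = 3.0, min_disp: float = 0.5,
               n_bins: int = 20) -> list:
    """Dispersion-based highly-variable-gene selection.

    Per gene, the mean and dispersion (variance / mean) are computed on the
    back-transformed values ``expm1(log_norm)``; the mean is carried on the
    ``log1p`` scale for the range thresholds.  Genes are cut into ``n_bins``
    equal-frequency bins by mean and dispersions are z-scored (plain
    mean/sd) within each bin.  A gene is selected iff its log-scale mean
    lies in ``[min_mean, max_mean]`` and its normalized dispersion is
    >= ``min_disp``.
    """
    X = _densify(log_norm)
    n_genes = X.shape[1]
    if gene_names is None:
        gene_names = [f"g{j}" for j in range(n_genes)]
    gene_names = np.asarray(gene_names)

    back = np.expm1(X)
    mean = back.mean(axis=0)
    var = back.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(n_genes)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    log_mean = np.log1p(mean)

    n_bins_eff = min(n_bins, max(np.unique(mean).size - 1, 1))
    try:
        bins = pd.qcut(mean, n_bins_eff, labels=False, duplicates="drop")
    except ValueError:
        bins = np.zeros(n_genes, dtype=int)
    bins = np.asarray(bins)

    disp_norm = np.zeros(n_genes)
    for b in np.unique(bins):
        m = bins == b
        mu = disp[m].mean()
        sd = disp[m].std(ddof=1) if m.sum() > 1 else 0.0
        disp_norm[m] = (disp[m] - mu) / sd if sd > 0 else 0.0

    selected = (log_mean >= min_mean) & (log_mean <= max_mean) & (disp_norm >= min_disp) & (disp > 0)
    return list(gene_names[selected])
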