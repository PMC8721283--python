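"""Receptor-ligand interaction testing between cluster pairs.

For an ordered (sender, receiver) cluster pair and a single-gene
ligand/receptor pair, the interaction score is the mean of the ligand's
mean expression in the sender and the receptor's mean expression in the
receiver — provided each partner is expressed (count > 0) in at least 30%
of the relevant cluster's cells, otherwise the score is not reported.  The
null distribution comes from shuffling the cluster label vector; one shared
set of seeded shuffles is reused for every pair so a run is jointly
reproducible.  The p-value uses the add-one convention
``(1 + #{null >= observed}) / (n_perm + 1)``, so the attainable minimum is
``1/(n_perm + 1)``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

__all__ = ["score_interactions"]


def score_interactions(log_norm, clusters, pairs: pd.DataFrame, n_perm: int = 1000,
                       expr_frac_min: float = 0.30, alpha: float = 0.05,
                       seed: int = 0, gene_names=None) -> pd.DataFrame:
    """Permutation test of ligand-receptor scores over all ordered cluster pairs.

    Parameters
    ----------
    log_norm : AnnData or (cells, genes) matrix
        Normalized expression.
    clusters : array-like
        Per-cell cluster labels, >= 2 clusters.
    pairs : pandas.DataFrame
        Columns ``ligand_gene`` and ``receptor_gene``; pairs with a gene
        absent from the matrix are reported with ``skipped=True``.
    n_perm : int
        Number of label shuffles (< 100 triggers a resolution warning).
    expr_frac_min : float
        Minimum fraction of cells with count > 0 required of the ligand in
        the sender and the receptor in the receiver.

    Returns
    -------
    pandas.DataFrame
        One row per (ligand, receptor, sender, receiver): ``score`` and
        ``p`` (NaN when the threshold rule failed), ``significant``
        (p < alpha), and ``skipped`` for absent genes.
    """
    if isinstance(log_norm, AnnData):
        gene_names = list(log_norm.var_names)
        X = log_norm.X
    else:
        X = log_norm
        if gene_names is None:
            raise ValueError("gene_names required when log_norm is a bare matrix")
        gene_names = list(gene_names)
    if sparse.issparse(X):
        X = np.asarray(X.todense())
    X = np.asarray(X, dtype=float)

    clusters = np.asarray(clusters)
    labels = pd.unique(clusters)
    if labels.size < 2:
        raise ValueError("need >= 2 clusters")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse p-value resolution")

    name_to_idx = {g: j for j, g in enumerate(gene_names)}
    used_genes = sorted({g for col in ("ligand_gene", "receptor_gene")
                         for g in pairs[col] if g in name_to_idx})
    gidx = {g: k for k, g in enumerate(used_genes)}
    sub = X[:, [name_to_idx[g] for g in used_genes]]  # cells x used genes

    onehot = np.stack([(clusters == lab).astype(float) for lab in labels])  # K x cells
    sizes = onehot.sum(axis=1)
    obs_means = (onehot @ sub) / sizes[:, None]                   # K x G
    frac_pos = (onehot @ (sub > 0)) / sizes[:, None]              # K x G

    rng = np.random.default_rng(seed)
    n_cells = X.shape[0]
    null_means = np.empty((n_perm, labels.size, len(used_genes)))
    for t in range(n_perm):
        perm = rng.permutation(n_cells)
        null_means[t] = (onehot[:, perm] @ sub) / sizes[:, None]

    lab_pos = {lab: i for i, lab in enumerate(labels)}
    rows = []
    for _, pr in pairs.iterrows():
        lig, rec = pr["ligand_gene"], pr["receptor_gene"]
        absent = lig not in name_to_idx or rec not in name_to_idx
        for a in labels:
            for b in labels:
                row = {"ligand_gene": lig, "receptor_gene": rec,
                       "sender": a, "receiver": b,
                       "score": np.nan, "p": np.nan,
                       "significant": False, "skipped": absent}
                if not absent:
                    ia, ib = lab_pos[a], lab_pos[b]
                    jl, jr = gidx[lig], gidx[rec]
                    if frac_pos[ia, jl] >= expr_frac_min and frac_pos[ib, jr] >= expr_frac_min:
                        score = 0.5 * (obs_means[ia, jl] + obs_means[ib, jr])
                        null = 0.5 * (null_means[:, ia, jl] + null_means[:, ib, jr])
                        p = (1.0 + np.sum(null >= score)) / (n_perm + 1.0)
                        row.update(score=score, p=p, significant=bool(p < alpha))
                rows.append(row)
    return pd.DataFrame(rows)
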