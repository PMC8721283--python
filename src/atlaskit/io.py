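"""Readers and writers for the plain-text formats the pipeline exchanges.

Count matrices travel as Matrix Market (.mtx, genes x cells, the droplet
convention) with ``genes.tsv`` / ``barcodes.tsv`` sidecars; everything else
is CSV.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse
from scipy.io import mmread, mmwrite

__all__ = [
    "write_counts_dir",
    "read_counts_dir",
    "write_spatial_csv",
    "read_spatial_csv",
    "write_cohort_csv",
    "read_cohort_csv",
]


def write_counts_dir(adata: AnnData, outdir) -> None:
    """Write counts as ``matrix.mtx`` (genes x cells) + gene/barcode TSVs;
    ``obs`` columns go to ``cells.csv``."""
    os.makedirs(outdir, exist_ok=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    mmwrite(os.path.join(outdir, "matrix.mtx"), X.T.tocoo())
    pd.Series(adata.var_names).to_csv(os.path.join(outdir, "genes.tsv"),
                                      sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(os.path.join(outdir, "barcodes.tsv"),
                                      sep="\t", index=False, header=False)
    if adata.obs.shape[1]:
        adata.obs.to_csv(os.path.join(outdir, "cells.csv"))


def read_counts_dir(indir) -> AnnData:
    """Read a directory written by :func:`write_counts_dir`."""
    X = mmread(os.path.join(indir, "matrix.mtx")).T.tocsr()
    genes = pd.read_csv(os.path.join(indir, "genes.tsv"), sep="\t", header=None)[0]
    barcodes = pd.read_csv(os.path.join(indir, "barcodes.tsv"), sep="\t", header=None)[0]
    obs = pd.DataFrame(index=barcodes.astype(str))
    cells_path = os.path.join(indir, "cells.csv")
    if os.path.exists(cells_path):
        obs = pd.read_csv(cells_path, index_col=0)
        obs.index = obs.index.astype(str)
    return AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes.astype(str)))


def write_spatial_csv(spatial: AnnData, path) -> None:
    """Flat spot table: spot_id, x, y, true proportions (if any), then genes."""
    coords = spatial.obsm["spatial"]
    df = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1]}, index=spatial.obs_names)
    if "proportions_true" in spatial.obsm:
        props = pd.DataFrame(spatial.obsm["proportions_true"], index=spatial.obs_names,
                             columns=[f"prop_{c}" for c in spatial.uns["classes"]])
        df = pd.concat([df, props], axis=1)
    X = spatial.X
    if sparse.issparse(X):
        X = np.asarray(X.todense())
    expr = pd.DataFrame(X, index=spatial.obs_names, columns=spatial.var_names)
    pd.concat([df, expr], axis=1).rename_axis("spot_id").to_csv(path)


def read_spatial_csv(path) -> AnnData:
    df = pd.read_csv(path, index_col="spot_id")
    coords = df[["x", "y"]].to_numpy(dtype=float)
    prop_cols = [c for c in df.columns if c.startswith("prop_")]
    gene_cols = [c for c in df.columns if c not in ("x", "y") and c not in prop_cols]
    adata = AnnData(X=df[gene_cols].to_numpy(dtype=float),
                    obs=pd.DataFrame(index=df.index.astype(str)),
                    var=pd.DataFrame(index=pd.Index(gene_cols)))
    adata.obsm["spatial"] = coords
    if prop_cols:
        adata.obsm["proportions_true"] = df[prop_cols].to_numpy(dtype=float)
        adata.uns["classes"] = [c[len("prop_"):] for c in prop_cols]
    return adata


def write_cohort_csv(cohort, path) -> None:
    """Flat cohort table (sample, time, event, genes...)."""
    cohort.to_table().to_csv(path)


def read_cohort_csv(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns ``(expression, survival)`` from a flat cohort table."""
    df = pd.read_csv(path, index_col=0)
    survival = df[["time", "event"]].copy()
    expression = df.drop(columns=["time", "event"])
    return expression, survival
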