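"""Per-cell gene-set scoring and group comparison.

Two complementary scores:

* :func:`module_score` — mean expression of the set minus the mean of an
  expression-bin-matched control pool (the classic module/signature score);
* :func:`auc_score` — the area under the recovery curve of set genes within
  each cell's top-ranked genes, normalized by the maximal attainable area
  (rank-based, hence invariant under monotone transforms of a cell's
  expression).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import sparse

from .stats import kruskal_wallis, mann_whitney

__all__ = ["GeneSet", "read_gmt", "module_score", "auc_score", "compare_scores"]


@dataclass(frozen=True)
class GeneSet:
    """A named list of gene identifiers."""

    name: str
    genes: tuple

    def intersect(self, gene_names) -> "GeneSet":
        present = [g for g in self.genes if g in set(gene_names)]
        return GeneSet(self.name, tuple(present))


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], tuple(g for g in parts[2:] if g)))
    return sets


def _dense(X):
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X, dtype=float)


class EmptyGeneSetError(ValueError):
    """Gene set has no genes in the matrix; caller should skip and report."""


def module_score(log_norm, gene_names, geneset: GeneSet, n_bins: int = 25,
                 ctrl_per_gene: int = 50, seed: int = 0) -> np.ndarray:
    """Bin-matched control module score per cell.

    All genes are cut into ``n_bins`` equal-frequency bins by mean
    expression; for each set gene, ``ctrl_per_gene`` control genes are
    sampled without replacement from its bin (seeded).  The score is the
    mean over set genes minus the mean over the (deduplicated) control
    pool, per cell.
    """
    X = _dense(log_norm)
    gene_names = list(gene_names)
    name_to_idx = {g: j for j, g in enumerate(gene_names)}
    gs = geneset.intersect(gene_names)
    if not gs.genes:
        raise EmptyGeneSetError(f"gene set {geneset.name!r} has no genes in the matrix")
    set_idx = np.array([name_to_idx[g] for g in gs.genes])

    mean = X.mean(axis=0)
    n_bins_eff = min(n_bins, max(np.unique(mean).size, 1))
    try:
        bins = pd.qcut(mean, n_bins_eff, labels=False, duplicates="drop")
    except ValueError:
        bins = np.zeros(mean.size, dtype=int)
    bins = np.asarray(bins)

    rng = np.random.default_rng(seed)
    ctrl: set[int] = set()
    for j in set_idx:
        pool = np.flatnonzero(bins == bins[j])
        take = min(ctrl_per_gene, pool.size)
        ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
    ctrl_idx = np.fromiter(ctrl, dtype=int)

    return X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)


def auc_score(expr, gene_names, geneset: GeneSet, top_fraction: float = 0.05,
              seed: int = 0, tie_break: str = "random") -> np.ndarray:
    """Recovery-curve AUC enrichment score per cell, in [0, 1].

    Genes are ranked descending by expression within each cell (ties broken
    by a seeded random permutation, or lexicographically by gene index with
    ``tie_break="index"``).  With ``T = ceil(top_fraction * n_genes)`` the
    recovery curve ``y(r)`` counts set genes at rank <= r; the score is
    ``sum_{r<=T} y(r)`` divided by its maximum (the set occupying the top
    ranks).
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must lie in (0, 1]")
    X = _dense(expr)
    gene_names = list(gene_names)
    gs = geneset.intersect(gene_names)
    if not gs.genes:
        raise EmptyGeneSetError(f"gene set {geneset.name!r} has no genes in the matrix")
    name_to_idx = {g: j for j, g in enumerate(gene_names)}
    in_set = np.zeros(X.shape[1], dtype=bool)
    in_set[[name_to_idx[g] for g in gs.genes]] = True

    n_cells, n_genes = X.shape
    T = ceil(top_fraction * n_genes)
    s = int(in_set.sum())
    # max attainable: y = (1, 2, ..., s, s, ...) summed to T
    max_auc = float(sum(min(r, s) for r in range(1, T + 1)))

    rng = np.random.default_rng(seed)
    if tie_break == "random":
        jitter = rng.random((n_cells, n_genes))
    elif tie_break == "index":
        jitter = np.tile(-np.arange(n_genes, dtype=float), (n_cells, 1))
    else:
        raise ValueError("tie_break must be 'random' or 'index'")

    # descending by expression; jitter only reorders within exact ties
    order = np.lexsort((-jitter, -X), axis=1)
    top = order[:, :T]
    hits = in_set[top]  # n_cells x T, True where rank r holds a set gene
    y = np.cumsum(hits, axis=1)
    return y.sum(axis=1) / max_auc


def compare_scores(scores, groups) -> dict:
    """Compare per-cell scores across groups.

    Two groups: two-sided Mann-Whitney U.  More: Kruskal-Wallis.  Empty
    groups are dropped.  Returns ``{"test": ..., "statistic": ..., "p": ...}``.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    groups = np.asarray(groups)
    if scores.size != groups.size:
        raise ValueError("scores and groups must have equal length")
    samples = [scores[groups == g] for g in pd.unique(groups)]
    samples = [s for s in samples if s.size > 0]
    if len(samples) < 2:
        raise ValueError("need >= 2 non-empty groups")
    if len(samples) == 2:
        u, p = mann_whitney(samples[0], samples[1], alternative="two-sided")
        return {"test": "mann-whitney", "statistic": u, "p": p}
    h, p = kruskal_wallis(samples)
    return {"test": "kruskal-wallis", "statistic": h, "p": p}
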