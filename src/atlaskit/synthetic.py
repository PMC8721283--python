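"""Synthetic data generation for the whole pipeline.

Three generators provide inputs with the statistical structure the
downstream stages assume:

* :func:`simulate_atlas` — a multi-cluster single-cell count matrix with
  planted marker genes, negative-binomial noise, log-normal library-size
  variation, and a planted doublet population with elevated doublet scores;
* :func:`simulate_spatial` — a 2-D spot grid whose expression is a mixture
  of the atlas cluster profiles under smooth per-cluster proportion fields;
* :func:`simulate_cohort` — bulk mixtures of the atlas cluster profiles with
  exponential survival times whose hazard depends on one cluster's
  proportion, plus independent exponential censoring.

All generators are fully reproducible from their ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse
from scipy import stats as sps

__all__ = [
    "AtlasConfig",
    "SpatialConfig",
    "CohortConfig",
    "Cohort",
    "ConfigError",
    "simulate_atlas",
    "simulate_spatial",
    "simulate_cohort",
    "cluster_profiles",
    "quartile_hazard_coefficient",
]

DOUBLET_LABEL = "doublet"


class ConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass
class AtlasConfig:
    """Configuration for the synthetic single-cell atlas.

    Counts are negative-binomial with a shared dispersion; per-gene base
    means are log-normal across genes (median ``baseline_mean``, spread
    ``gene_mean_sigma`` log-units — real transcriptomes span orders of
    magnitude in mean expression, and mean-binned HVG selection assumes
    that spread); each cluster gets a disjoint block of marker genes whose
    mean is multiplied by ``marker_fold_change``; per-cell library-size
    factors are log-normal.
    Doublets are planted by summing two singlet parents from different
    clusters, and carry high doublet scores (Beta(8, 2)) versus singlets
    (Beta(2, 8)) — overlapping enough that flagging is non-trivial.
    """

    n_clusters: int = 5
    cells_per_cluster: int = 200
    n_genes: int = 1000
    markers_per_cluster: int = 30
    marker_fold_change: float = 4.0
    nb_dispersion: float = 2.0
    baseline_mean: float = 0.5
    gene_mean_sigma: float = 1.0
    doublet_fraction: float = 0.08
    mito_gene_count: int = 10
    mito_high_fraction: float = 0.0
    mito_high_share: float = 0.5
    library_size_sigma: float = 0.3
    doublet_mode: str = "separate"  # or "parent"
    seed: int = 0
    #: seed for the structural parameters (per-gene base means); defaults to
    #: ``seed``.  Fixing it while varying ``seed`` regenerates the same
    #: generative model with fresh sampling noise.
    structure_seed: Optional[int] = None

    def validate(self) -> None:
        if self.n_clusters < 1 or self.cells_per_cluster < 1 or self.n_genes < 1:
            raise ConfigError("counts must be positive")
        if not (0.0 <= self.doublet_fraction <= 1.0):
            raise ConfigError("doublet_fraction must lie in [0, 1]")
        if self.marker_fold_change <= 1.0:
            raise ConfigError("marker_fold_change must exceed 1")
        if self.nb_dispersion <= 0 or self.baseline_mean <= 0:
            raise ConfigError("nb_dispersion and baseline_mean must be positive")
        if self.markers_per_cluster * self.n_clusters + self.mito_gene_count > self.n_genes:
            raise ConfigError("marker and mito genes exceed n_genes")
        if self.doublet_mode not in ("separate", "parent"):
            raise ConfigError("doublet_mode must be 'separate' or 'parent'")
        if not (0.0 <= self.mito_high_fraction <= 1.0):
            raise ConfigError("mito_high_fraction must lie in [0, 1]")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # numpy parameterization: n = dispersion, p = n / (n + mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_atlas(config: AtlasConfig) -> AnnData:
    """Generate the synthetic single-cell atlas.

    Returns
    -------
    anndata.AnnData
        Sparse integer counts with per-cell truth in ``.obs``
        (``cluster``, ``true_cluster``, ``is_doublet``, ``doublet_score``)
        and the planted marker map in ``.uns["marker_map"]``.  ``cluster``
        equals ``true_cluster`` for singlets; doublets are labelled
        ``"doublet"`` (default) or inherit a parent label, depending on
        ``doublet_mode``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    K, n_per, G = config.n_clusters, config.cells_per_cluster, config.n_genes
    n_cells = K * n_per

    gene_names = np.array(
        [f"MT-{i + 1}" for i in range(config.mito_gene_count)]
        + [f"GENE{i + 1:04d}" for i in range(G - config.mito_gene_count)]
    )
    # disjoint marker blocks, drawn from the non-mito genes
    marker_map: dict[str, list[str]] = {}
    start = config.mito_gene_count
    struct_rng = np.random.default_rng(
        config.seed if config.structure_seed is None else config.structure_seed)
    base_means = config.baseline_mean * np.exp(
        struct_rng.normal(0.0, config.gene_mean_sigma, size=G))
    mean_profiles = np.tile(base_means, (K, 1))
    for c in range(K):
        idx = np.arange(start + c * config.markers_per_cluster,
                        start + (c + 1) * config.markers_per_cluster)
        mean_profiles[c, idx] *= config.marker_fold_change
        marker_map[f"cluster_{c}"] = list(gene_names[idx])

    clusters = np.repeat(np.arange(K), n_per)
    lib = np.exp(rng.normal(0.0, config.library_size_sigma, size=n_cells))

    mean_mat = mean_profiles[clusters] * lib[:, None]
    if config.mito_high_fraction > 0:
        # inflate the mito share of a random subset of cells (QC fixture)
        hi = rng.random(n_cells) < config.mito_high_fraction
        mito_idx = np.arange(config.mito_gene_count)
        non_mito_total = mean_mat[:, config.mito_gene_count:].sum(axis=1)
        s = config.mito_high_share
        target = s / (1.0 - s) * non_mito_total / max(config.mito_gene_count, 1)
        mean_mat[np.ix_(hi, mito_idx)] = target[hi, None]
        mito_high = hi
    else:
        mito_high = np.zeros(n_cells, dtype=bool)

    counts = _nb_sample(rng, mean_mat, config.nb_dispersion)

    is_doublet = rng.random(n_cells) < config.doublet_fraction
    labels = np.array([f"cluster_{c}" for c in clusters], dtype=object)
    true_labels = labels.copy()
    singlet_idx = np.flatnonzero(~is_doublet)
    for i in np.flatnonzero(is_doublet):
        # two distinct singlet parents from different clusters
        p1 = rng.choice(singlet_idx)
        other = singlet_idx[clusters[singlet_idx] != clusters[p1]]
        p2 = rng.choice(other)
        counts[i] = counts[p1] + counts[p2]
        true_labels[i] = DOUBLET_LABEL
        labels[i] = DOUBLET_LABEL if config.doublet_mode == "separate" else labels[p1]

    score = np.where(is_doublet, rng.beta(8, 2, size=n_cells), rng.beta(2, 8, size=n_cells))

    obs = pd.DataFrame({
        "cluster": labels,
        "true_cluster": true_labels,
        "is_doublet": is_doublet,
        "doublet_score": score,
        "mito_high": mito_high,
    }, index=[f"cell_{i:05d}" for i in range(n_cells)])
    adata = AnnData(
        X=sparse.csr_matrix(counts.astype(np.int64)),
        obs=obs,
        var=pd.DataFrame(index=gene_names),
    )
    adata.uns["marker_map"] = marker_map
    return adata


def cluster_profiles(adata: AnnData, labels=None, exclude_doublets: bool = True) -> pd.DataFrame:
    """Per-cluster mean count profiles (classes x genes).

    Doublets (per the truth annotation) are excluded by default so profiles
    describe the pure populations.
    """
    if labels is None:
        labels = adata.obs["cluster"].to_numpy()
    labels = np.asarray(labels)
    X = adata.X
    if sparse.issparse(X):
        X = np.asarray(X.todense())
    keep = np.ones(adata.n_obs, dtype=bool)
    if exclude_doublets and "is_doublet" in adata.obs:
        keep = ~adata.obs["is_doublet"].to_numpy()
    profiles = {}
    for cl in pd.unique(labels[keep]):
        if cl == DOUBLET_LABEL:
            continue
        profiles[cl] = X[keep & (labels == cl)].mean(axis=0)
    return pd.DataFrame(profiles, index=adata.var_names).T


# ---------------------------------------------------------------------------
# spatial


@dataclass
class SpatialConfig:
    """Configuration for the synthetic spot grid.

    The default layout mimics tissue sections where one structural
    compartment dominates every spot and the focal cell types vary as
    minor fractions: the last cluster gets a constant background weight,
    cluster 0 a smooth cosine field varying only along x, cluster 1 one
    varying only along y (so their fields are orthogonal over the grid and
    vary everywhere), and any remaining clusters Gaussian bumps at spread
    centers.  Weights are normalized spot-wise to the unit simplex.
    ``fields`` may be a list of callables ``f(x, y) -> weight``
    (vectorized over unit-square coordinates, non-negative) to override
    the default layout.
    """

    grid_width: int = 20
    grid_height: int = 20
    fields: Optional[Sequence[Callable]] = None
    bump_amplitude: float = 1.5
    bump_sigma: float = 0.25
    floor: float = 0.2
    background_weight: float = 10.0
    noise_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.grid_width < 1 or self.grid_height < 1:
            raise ConfigError("grid dimensions must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")


def _default_fields(K: int, amp: float, sig: float, floor: float, background: float):
    """Default weight-field layout on the unit square.

    Cluster 0 varies along x only and cluster 1 along y only (cosine
    fields, active everywhere); the last cluster is a constant dominant
    background; anything in between gets a Gaussian bump.
    """
    fields = [
        lambda x, y: floor + amp * 0.5 * (1.0 + np.cos(2 * np.pi * (x - 0.1))),
        lambda x, y: floor + amp * 0.5 * (1.0 + np.cos(2 * np.pi * (y - 0.1))),
    ]
    centers = np.linspace(0.2, 0.8, max(K - 3, 1))
    for i in range(max(K - 3, 0)):
        def f(x, y, cx=centers[i], cy=1.0 - centers[i]):
            d2 = (x - cx) ** 2 + (y - cy) ** 2
            return floor + amp * np.exp(-d2 / (2 * sig ** 2))
        fields.append(f)
    fields.append(lambda x, y: background * np.ones_like(np.asarray(x, dtype=float)))
    return fields[:K] if K >= 2 else fields[:1]


def simulate_spatial(config: SpatialConfig, atlas: AnnData) -> AnnData:
    """Generate spot-level expression from smooth cluster-proportion fields.

    Each spot's expression is the proportion-weighted mixture of the atlas
    cluster mean profiles plus zero-truncated Gaussian noise.

    Returns
    -------
    anndata.AnnData
        Spots x genes, with coordinates in ``.obsm["spatial"]`` and the true
        simplex proportions in ``.obsm["proportions_true"]`` (classes listed
        in ``.uns["classes"]``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    profiles = cluster_profiles(atlas)
    classes = list(profiles.index)
    K = len(classes)

    W, H = config.grid_width, config.grid_height
    gx, gy = np.meshgrid(np.arange(W), np.arange(H), indexing="ij")
    gx, gy = gx.ravel(), gy.ravel()
    # unit-square coordinates drive the fields; stored coords are grid units
    ux = gx / max(W - 1, 1)
    uy = gy / max(H - 1, 1)

    fns = config.fields
    if fns is None:
        fns = _default_fields(K, config.bump_amplitude, config.bump_sigma,
                              config.floor, config.background_weight)
    if len(fns) != K:
        raise ConfigError(f"need {K} fields, got {len(fns)}")
    weights = np.stack([np.maximum(np.asarray(f(ux, uy), dtype=float), 0.0) for f in fns], axis=1)
    tot = weights.sum(axis=1, keepdims=True)
    if np.any(tot <= 0):
        raise ConfigError("proportion fields must be positive somewhere at every spot")
    props = weights / tot

    expr = props @ profiles.to_numpy()
    if config.noise_sd > 0:
        expr = np.maximum(expr + rng.normal(0.0, config.noise_sd, size=expr.shape), 0.0)

    n = W * H
    adata = AnnData(
        X=expr,
        obs=pd.DataFrame(index=[f"spot_{i:04d}" for i in range(n)]),
        var=pd.DataFrame(index=profiles.columns),
    )
    adata.obsm["spatial"] = np.column_stack([gx, gy]).astype(float)
    adata.obsm["proportions_true"] = props
    adata.uns["classes"] = classes
    return adata


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortConfig:
    """Configuration for the synthetic bulk survival cohort.

    Per-sample cluster proportions are Dirichlet; bulk expression is the
    proportion-weighted mixture of cluster profiles with multiplicative
    Gaussian noise (``noise_sd`` is a relative level, e.g. 0.05 = 5%).
    Event times are exponential with rate
    ``baseline_hazard * exp(beta * p_hazard)`` where ``p_hazard`` is the
    hazard cluster's proportion; censoring is independent exponential.

    ``log_hazard_ratio_per_unit`` of ``None`` resolves to the coefficient
    that plants a hazard ratio of 2 between the top- and bottom-quartile
    strata of the hazard proportion (see
    :func:`quartile_hazard_coefficient`).
    """

    n_samples: int = 400
    proportion_prior: Optional[np.ndarray] = None  # defaults to Dirichlet(2,...,2)
    noise_sd: float = 0.05
    hazard_cluster: str = "cluster_0"
    log_hazard_ratio_per_unit: Optional[float] = None
    baseline_hazard: float = 0.1
    censor_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be positive")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be positive")
        if self.censor_rate <= 0:
            raise ConfigError("censor_rate must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")


def quartile_hazard_coefficient(alpha: np.ndarray, hazard_index: int,
                                group_hazard_ratio: float = 2.0) -> float:
    """Per-unit log-hazard coefficient planting a given between-strata HR.

    Under a Dirichlet prior the hazard cluster's proportion is marginally
    Beta(a, A - a).  The expected gap between the top- and bottom-quartile
    conditional means of that Beta is computed analytically (truncated-Beta
    means), and the coefficient is ``log(HR) / gap`` so that stratifying at
    the quartiles plants a hazard ratio of ``group_hazard_ratio`` between
    the high and low groups.
    """
    alpha = np.asarray(alpha, dtype=float)
    a = alpha[hazard_index]
    b = alpha.sum() - a
    q25, q75 = sps.beta.ppf([0.25, 0.75], a, b)
    mu = a / (a + b)
    upper = mu * sps.beta.sf(q75, a + 1, b) / 0.25
    lower = mu * sps.beta.cdf(q25, a + 1, b) / 0.25
    return float(np.log(group_hazard_ratio) / (upper - lower))


@dataclass
class Cohort:
    """Synthetic bulk cohort: expression, survival and truth proportions."""

    expression: pd.DataFrame   # samples x genes
    survival: pd.DataFrame     # columns: time, event
    proportions_true: pd.DataFrame  # samples x classes
    hazard_cluster: str

    def to_table(self) -> pd.DataFrame:
        """Single flat table: sample, time, event, then gene columns."""
        return pd.concat([self.survival, self.expression], axis=1)


def simulate_cohort(config: CohortConfig, atlas: AnnData) -> Cohort:
    """Generate the synthetic bulk survival cohort from the atlas profiles."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    profiles = cluster_profiles(atlas)
    classes = list(profiles.index)
    if config.hazard_cluster not in classes:
        raise ConfigError(f"hazard_cluster {config.hazard_cluster!r} not in atlas")
    K = len(classes)
    alpha = (np.full(K, 2.0) if config.proportion_prior is None
             else np.asarray(config.proportion_prior, dtype=float))
    if alpha.size != K or np.any(alpha <= 0):
        raise ConfigError("proportion_prior must give one positive value per cluster")

    h_idx = classes.index(config.hazard_cluster)
    beta = config.log_hazard_ratio_per_unit
    if beta is None:
        beta = quartile_hazard_coefficient(alpha, h_idx)

    props = rng.dirichlet(alpha, size=config.n_samples)
    expr = props @ profiles.to_numpy()
    if config.noise_sd > 0:
        expr = np.maximum(expr * (1.0 + rng.normal(0.0, config.noise_sd, size=expr.shape)), 0.0)

    rate = config.baseline_hazard * np.exp(beta * props[:, h_idx])
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.exponential(1.0 / config.censor_rate, size=config.n_samples)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    idx = pd.Index([f"sample_{i:04d}" for i in range(config.n_samples)], name="sample")
    return Cohort(
        expression=pd.DataFrame(expr, index=idx, columns=profiles.columns),
        survival=pd.DataFrame({"time": time, "event": event}, index=idx),
        proportions_true=pd.DataFrame(props, index=idx, columns=classes),
        hazard_cluster=config.hazard_cluster,
    )
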