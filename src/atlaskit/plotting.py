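"""Minimal plotting helpers for survival curves and spatial correlation maps."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_km", "plot_spatial_correlation"]


def plot_km(fit, ax=None):
    """Step plot of Kaplan-Meier curves per group.

    Parameters
    ----------
    fit : SurvivalFit
        Output of :func:`atlaskit.survival.km_estimate`.
    ax : matplotlib axes, optional
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for group, curve in fit.curves.items():
        t = np.r_[0.0, curve["time"].to_numpy()]
        s = np.r_[1.0, curve["survival"].to_numpy()]
        ax.step(t, s, where="post", label=str(group))
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    return ax


def plot_spatial_correlation(coords, result, ax=None, cmap="Reds", size=30):
    """Scatter map of per-spot neighborhood correlations (positives only,
    the convention for these maps; excluded spots drawn in light grey).

    Parameters
    ----------
    coords : (spots, 2) array
        Spot coordinates.
    result : ColocResult
        Output of :func:`atlaskit.spatial.neighborhood_correlation`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    coords = np.asarray(coords, dtype=float)
    vals = result.per_spot_positive
    missing = np.isnan(vals)
    ax.scatter(coords[missing, 0], coords[missing, 1], c="0.9", s=size)
    sc = ax.scatter(coords[~missing, 0], coords[~missing, 1], c=vals[~missing],
                    cmap=cmap, vmin=0, vmax=1, s=size)
    plt.colorbar(sc, ax=ax, label="neighborhood correlation")
    ax.set_aspect("equal")
    return ax
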