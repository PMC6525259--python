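"""Static diagnostic plots (scree and projected simplex scatter)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_scree", "plot_simplex"]


def plot_scree(results, n_components: int = 10, ax=None):
    """Bar plot of centered explained variance with the cumulative curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    tab = results.scree_centered.head(n_components)
    ax.bar(tab["component"], tab["explained_variance"], color="#4878a8")
    ax.plot(tab["component"], tab["cumulative"], "o-", color="#b04030", ms=3)
    ax.axhline(results.config.cumulative_threshold, ls="--", lw=0.8, color="gray")
    ax.set_xlabel("component")
    ax.set_ylabel("explained variance")
    ax.set_title(f"centered scree (K = {results.k_types})")
    return ax


def plot_simplex(results, dims: tuple[int, int] = (0, 1), ax=None):
    """Scatter of projected genes with corners; first two projected
    dimensions by default (only dimension 0 for K = 2)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.2, 4))
    pts = results.projection.projected
    corners = results.solution.corners_projected
    if pts.shape[0] == 1:
        ax.scatter(pts[0], np.zeros(pts.shape[1]), s=3, alpha=0.3, color="#555")
        ax.scatter(corners[:, 0], np.zeros(len(corners)), s=60, marker="^",
                   color="#b04030", zorder=3)
        ax.set_xlabel("projected dim 1")
    else:
        i, j = dims
        ax.scatter(pts[i], pts[j], s=3, alpha=0.3, color="#555")
        closed = np.vstack([corners, corners[:1]])
        ax.plot(closed[:, i], closed[:, j], "-", color="#b04030", lw=1)
        ax.scatter(corners[:, i], corners[:, j], s=60, marker="^",
                   color="#b04030", zorder=3)
        ax.set_xlabel(f"projected dim {i + 1}")
        ax.set_ylabel(f"projected dim {j + 1}")
    ax.set_title("transcriptional simplex")
    return ax
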