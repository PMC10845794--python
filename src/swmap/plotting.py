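"""Heat maps and bias-curve figures."""

from __future__ import annotations

import numpy as np

from .grid import GRID_COLS, GRID_ROWS, values_to_grid
from .model import interpolate_map


def plot_weight_heatmap(values, significant=None, upsample_factor: int = 10,
                        ax=None, cmap: str = "RdBu_r", title: str | None = None):
    """Interpolated heat map of a 25-location map; asterisks mark
    significant locations."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    dense = interpolate_map(values, upsample_factor)
    vmax = np.nanmax(np.abs(dense)) or 1.0
    im = ax.imshow(dense, cmap=cmap, vmin=-vmax, vmax=vmax,
                   extent=(-0.5, GRID_COLS - 0.5, GRID_ROWS - 0.5, -0.5))
    if significant is not None:
        sig = values_to_grid(np.asarray(significant, dtype=float))
        for r in range(GRID_ROWS):
            for c in range(GRID_COLS):
                if sig[r, c]:
                    ax.text(c, r, "*", ha="center", va="center", fontsize=16)
    ax.set_xticks(range(GRID_COLS))
    ax.set_yticks(range(GRID_ROWS))
    if title:
        ax.set_title(title)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax


def plot_bias_curve(curve, axes=None):
    """Two-panel figure: error SD (top) and central bias (bottom) over the
    folded orientation axis, with across-subject SEM bands."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 1, sharex=True, figsize=(5, 5))
    x = curve.window_centers
    for ax, mat, color, label in (
        (axes[0], curve.per_subject_error_sd, "0.4", "error SD (deg)"),
        (axes[1], curve.per_subject_bias, "tab:green", "central bias (t units)"),
    ):
        mean = np.nanmean(mat, axis=0)
        n = np.sum(np.isfinite(mat), axis=0)
        sem = np.nanstd(mat, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
        ax.plot(x, mean, color=color)
        ax.fill_between(x, mean - sem, mean + sem, color=color, alpha=0.3)
        ax.set_ylabel(label)
    axes[1].set_xlabel("folded ensemble orientation (deg; 0/90 = cardinal)")
    return axes


def plot_serial_matrix(matrix, ax=None, cmap: str = "viridis"):
    """Heat map of a location x serial-position weight matrix."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.matrix, aspect="auto", cmap=cmap)
    ax.set_xlabel("serial-position window start")
    ax.set_ylabel("location")
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax
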