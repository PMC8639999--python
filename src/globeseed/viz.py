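"""Plot helpers: importance bars, partial-effect curves, semivariograms, maps.

Thin wrappers over matplotlib; every function writes a file and returns the
path so the CLI can report artifacts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_importance(importance, path: str | Path, metric: str = "node_purity") -> Path:
    """Horizontal bar chart of a ForestFit importance table, largest on top."""
    plt = _plt()
    tab = importance.sort_values(metric)
    fig, ax = plt.subplots(figsize=(6, 0.28 * len(tab) + 1))
    ax.barh(tab.index, tab[metric], color="#4c72b0")
    ax.set_xlabel(
        "increase in node purity" if metric == "node_purity" else "% increase in MSE"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_partial_effects(effects: Sequence, path: str | Path, ncols: int = 3) -> Path:
    """Grid of partial-dependence curves (one panel per predictor)."""
    plt = _plt()
    n = len(effects)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows), squeeze=False)
    for ax, pe in zip(axes.ravel(), effects):
        ax.plot(pe.grid, pe.effect, color="#2a7e43")
        ax.set_xlabel(pe.predictor)
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_semivariogram(sv, path: str | Path) -> Path:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(sv.bin_centers, sv.gamma, "o-", color="#4c72b0")
    ax.axhline(sv.sample_variance, ls="--", color="grey", label="sample variance")
    ax.set_xlabel("lag (km)")
    ax.set_ylabel("semivariance")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_raster(raster, path: str | Path, title: str = "") -> Path:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    extent = [raster.lon[0], raster.lon[-1], raster.lat[-1], raster.lat[0]]
    im = ax.imshow(raster.values, extent=extent, aspect="auto", cmap="viridis")
    fig.colorbar(im, ax=ax)
    if title:
        ax.set_title(title)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
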