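"""Optional figures: spectrum overlay and hetmer-pair heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .kmercount import KmerHistogram
from .smudge import HetmerGrid
from .spectrumfit import SpectrumFit, model_density


def plot_spectrum(
    hist: KmerHistogram,
    fit: SpectrumFit | None = None,
    path: str | Path | None = None,
    x_max: int | None = None,
):
    """K-mer spectrum with an optional fitted-model overlay."""
    fig, ax = plt.subplots(figsize=(7, 4))
    dense = hist.dense()
    top = x_max or (fit.fit_range[1] if fit else hist.max_depth)
    x = np.arange(1, min(top, hist.max_depth) + 1)
    ax.plot(x, dense[x], drawstyle="steps-mid", label="observed")
    if fit is not None:
        ax.plot(x, model_density(x, fit.params, fit.k), label="model")
        ax.axvline(fit.params.lam, ls="--", c="grey", lw=0.8)
        ax.axvline(2 * fit.params.lam, ls=":", c="grey", lw=0.8)
    ax.set_xlabel("k-mer depth")
    ax.set_ylabel("distinct k-mers")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_smudge(grid: HetmerGrid, path: str | Path | None = None):
    """Heatmap of hetmer-pair mass over (minor ratio, coverage sum)."""
    fig, ax = plt.subplots(figsize=(6, 5))
    extent = (
        0.0, 0.5,
        float(grid.total_edges[0]), float(grid.total_edges[-1] + grid.lam / 4),
    )
    ax.imshow(
        grid.bins.T, origin="lower", aspect="auto", extent=extent,
        cmap="viridis",
    )
    ax.set_xlabel("minor allele coverage ratio")
    ax.set_ylabel("pair coverage sum")
    if grid.ploidy_call:
        ax.set_title(f"call: {grid.ploidy_call}")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
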