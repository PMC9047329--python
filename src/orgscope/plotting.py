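"""Optional matplotlib visualizations of pipeline outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .mito_lineage import LOW_COVERAGE, MUTANT, WILD_TYPE


def cnv_heatmap(profile: pd.DataFrame, path=None, cmap="RdBu_r", vmax=None):
    """Cells x windows heatmap of relative CNV scores."""
    data = profile.T.to_numpy(dtype=float)
    vmax = vmax or np.nanmax(np.abs(data)) or 1.0
    fig, ax = plt.subplots(figsize=(max(6, profile.shape[0] / 5), max(4, profile.shape[1] / 20)))
    im = ax.imshow(data, aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xlabel("genomic window")
    ax.set_ylabel("cell")
    fig.colorbar(im, ax=ax, label="relative CNV score")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def mito_state_heatmap(states: pd.DataFrame, path=None):
    """Cells x sites heatmap: red mutant, blue wild type, gray low coverage."""
    code = {MUTANT: 2, WILD_TYPE: 1, LOW_COVERAGE: 0}
    data = states.replace(code).to_numpy(dtype=float)
    cmap = matplotlib.colors.ListedColormap(["#bdbdbd", "#3b6fb6", "#c0392b"])
    fig, ax = plt.subplots(figsize=(max(4, states.shape[1] / 2), max(4, states.shape[0] / 15)))
    ax.imshow(data, aspect="auto", cmap=cmap, vmin=0, vmax=2)
    ax.set_xticks(range(states.shape[1]))
    ax.set_xticklabels(states.columns, rotation=90, fontsize=7)
    ax.set_ylabel("cell")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def wgs_scatter(table: pd.DataFrame, sample: str, path=None):
    """Per-chromosome scatter of windowed copy-number ratios for one sample."""
    sub = table[table["sample"] == sample]
    fig, ax = plt.subplots(figsize=(10, 3))
    x = np.arange(len(sub))
    ax.scatter(x, sub["ratio"], s=8)
    ax.axhline(1.0, color="gray", lw=0.8)
    ax.set_ylabel("depth ratio")
    ax.set_title(sample)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
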