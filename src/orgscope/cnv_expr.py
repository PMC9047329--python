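"""Expression-inferred relative copy number (inferCNV-style).

Copy-number signal is read out of the transcriptome by smoothing
relative expression along the genome: each gene's CNV score is the mean
relative expression of its ~100 ordinal neighbours on the same
chromosome, centered across cells, then averaged within fixed 10-Mb
genomic windows to give a per-cell relative CNV profile. No HMM
segmentation or reference-baseline subtraction is applied.
"""

from __future__ import annotations

from typing import Optional
import warnings

import numpy as np
import pandas as pd

from .containers import WINDOW_BP, genomic_window_index


def relative_expression(tpm: pd.DataFrame) -> pd.DataFrame:
    """Relative expression E = log2(TPM/10 + 1)."""
    return np.log2(tpm / 10.0 + 1.0)


def filter_cnv_genes(
    tpm: pd.DataFrame, min_avg_rel_expr: float = 1.5
) -> list[str]:
    """Genes whose mean relative expression across QC-passed cells exceeds 1.5.

    The threshold is strict (> 1.5); lowly expressed genes carry mostly
    dropout noise and would dilute the moving-average signal.
    """
    E = relative_expression(tpm)
    keep = E.mean(axis=1) > min_avg_rel_expr
    genes = list(tpm.index[keep])
    if not genes:
        raise ValueError(
            "no gene passes the relative-expression filter; lower min_avg_rel_expr"
        )
    return genes


def gene_cnv_scores(
    E: pd.DataFrame, track: pd.DataFrame, k: int = 100
) -> pd.DataFrame:
    """Per-gene per-cell CNV scores: genomic moving average then centering.

    For each gene the score is the mean of E over the window of the k
    nearest genes in ordinal terms on the same chromosome (k/2 per side,
    including the gene itself, shrunk at chromosome ends — windows never
    cross chromosomes). Each gene's scores are then centered by
    subtracting its mean over all cells, so cross-cell structure, not
    absolute expression, remains.
    """
    track = track.loc[E.index]
    half = k // 2
    out = np.empty(E.shape)
    arr = E.to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(E.index)}
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("ordinal")
        idx = np.array([pos[g] for g in sub.index])
        n = len(idx)
        if n == 1:
            out[idx[0]] = arr[idx[0]]
            warnings.warn(f"{chrom}: single gene, degenerate CNV window")
            continue
        block = arr[idx]  # genes on this chromosome, ordered
        csum = np.vstack([np.zeros((1, block.shape[1])), np.cumsum(block, axis=0)])
        for j in range(n):
            lo, hi = max(0, j - half), min(n, j + half + 1)
            out[idx[j]] = (csum[hi] - csum[lo]) / (hi - lo)
    scores = pd.DataFrame(out, index=E.index, columns=E.columns)
    return scores.sub(scores.mean(axis=1), axis=0)


def window_cnv(
    scores: pd.DataFrame,
    track: pd.DataFrame,
    window_bp: int = WINDOW_BP,
) -> pd.DataFrame:
    """Average gene CNV scores within fixed genomic windows.

    Windows are half-open [i*window_bp, (i+1)*window_bp) anchored at 0
    on each chromosome; windows containing no scored gene are absent
    from the result (missing, not zero). Rows are a (chrom, widx)
    MultiIndex; columns are cells.
    """
    track = track.loc[scores.index]
    widx = genomic_window_index(track["start"].to_numpy(), window_bp)
    keys = pd.MultiIndex.from_arrays(
        [track["chrom"], widx], names=["chrom", "widx"]
    )
    profile = scores.groupby(keys).mean()
    profile.index = pd.MultiIndex.from_tuples(profile.index, names=["chrom", "widx"])
    return profile.sort_index()


def cnv_profile(
    tpm: pd.DataFrame,
    track: pd.DataFrame,
    min_avg_rel_expr: float = 1.5,
    k: int = 100,
    window_bp: int = WINDOW_BP,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full expression-CNV pipeline: filter, smooth, center, window.

    Returns (window profile, per-gene score matrix).
    """
    genes = filter_cnv_genes(tpm, min_avg_rel_expr)
    E = relative_expression(tpm.loc[genes])
    scores = gene_cnv_scores(E, track.loc[genes], k=k)
    return window_cnv(scores, track.loc[genes], window_bp), scores
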