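"""Windowed WGS read-depth copy-number ratios.

The genome is tiled into fixed 10-Mb windows; reads are counted per
window per sample and normalized in two stages: first by each sample's
total read depth (removing library size), then by the cross-sample mean
of the depth-normalized values per window (removing locus effects),
leaving a relative copy ratio whose cross-sample mean is 1 in every
window. Both the ratio and ratio x 2 (a diploid-scale copy number) are
reported.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import WINDOW_BP


def count_windows(
    positions: Mapping[str, tuple[Sequence[str], Sequence[int]]] | pd.DataFrame,
    genome: Sequence[tuple[str, int]],
    window_bp: int = WINDOW_BP,
) -> pd.DataFrame:
    """Raw read counts per (chrom, window) per sample.

    ``positions`` maps sample id -> (chromosomes, start positions), or is
    a long DataFrame with columns (sample, chrom, pos). A read belongs to
    the half-open window containing its start: window = pos // window_bp.
    Unknown chromosomes and out-of-bounds positions are errors.
    """
    lengths = dict(genome)
    windows = [
        (chrom, w)
        for chrom, length in genome
        for w in range(int(np.ceil(length / window_bp)))
    ]
    index = pd.MultiIndex.from_tuples(windows, names=["chrom", "widx"])

    if isinstance(positions, pd.DataFrame):
        grouped = {
            s: (sub["chrom"].tolist(), sub["pos"].tolist())
            for s, sub in positions.groupby("sample")
        }
    else:
        grouped = dict(positions)

    out = pd.DataFrame(0, index=index, columns=sorted(grouped), dtype=np.int64)
    for sample, (chroms, pos) in grouped.items():
        chroms = np.asarray(chroms)
        pos = np.asarray(pos, dtype=np.int64)
        for chrom in np.unique(chroms):
            if chrom not in lengths:
                raise KeyError(f"unknown chromosome {chrom!r}")
            p = pos[chroms == chrom]
            if (p < 0).any() or (p >= lengths[chrom]).any():
                raise ValueError(f"position outside {chrom} bounds")
            widx, n = np.unique(p // window_bp, return_counts=True)
            for w, c in zip(widx, n):
                out.loc[(chrom, int(w)), sample] += int(c)
    return out


def normalize_windows(raw: pd.DataFrame) -> pd.DataFrame:
    """Two-stage normalization of per-window counts across samples.

    Stage 1: norm1 = count / sample total (per-sample depth removed).
    Stage 2: ratio = norm1 / cross-sample mean of norm1 for the window.
    Windows whose cross-sample mean is zero get missing ratios. Returns
    a long table (sample, chrom, widx, raw, norm1, ratio, copy_number)
    with copy_number = 2 x ratio.
    """
    if raw.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    totals = raw.sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = list(raw.columns[totals <= 0])
        raise ValueError(f"samples with zero total reads: {bad}")
    norm1 = raw / totals
    ref = norm1.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = norm1.div(ref.where(ref > 0), axis=0)
    long = (
        pd.concat(
            {"raw": raw.stack(), "norm1": norm1.stack(), "ratio": ratio.stack()},
            axis=1,
        )
        .rename_axis(["chrom", "widx", "sample"])
        .reset_index()
    )
    long["copy_number"] = 2.0 * long["ratio"]
    return long


def wgs_cnv(
    raw: pd.DataFrame,
    reference_samples: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Normalize, optionally against a normals-only reference panel.

    With ``reference_samples`` the stage-2 reference is the mean of the
    named (e.g. normal) samples only, avoiding the bias introduced when
    tumor samples contribute to their own reference.
    """
    if reference_samples is None:
        return normalize_windows(raw)
    missing = [s for s in reference_samples if s not in raw.columns]
    if missing:
        raise KeyError(f"unknown reference samples: {missing}")
    totals = raw.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise ValueError("samples with zero total reads")
    norm1 = raw / totals
    ref = norm1[list(reference_samples)].mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = norm1.div(ref.where(ref > 0), axis=0)
    long = (
        pd.concat(
            {"raw": raw.stack(), "norm1": norm1.stack(), "ratio": ratio.stack()},
            axis=1,
        )
        .rename_axis(["chrom", "widx", "sample"])
        .reset_index()
    )
    long["copy_number"] = 2.0 * long["ratio"]
    return long
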