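"""Cell-level QC, marker typing, differential-gene selection and signatures.

Cells are kept when they detect more than ``min_genes`` genes and their
second-highest Pearson correlation to any other cell (on log2(TPM+1))
exceeds ``min_top2_corr`` — the outlier filter. Cell types are assigned
by marker score: epithelium (EPCAM), mesenchyme (VIM, THY1), immune
(PTPRC), with epithelial subtypes Goblet (MUC2), Enterocyte (CA2,
FABP1) and stem-like (LGR5, MKI67, OLFM4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MAJOR_TYPE_ORDER = ("epithelial", "mesenchymal", "immune")

DEFAULT_MARKERS: dict[str, tuple[str, ...]] = {
    "epithelial": ("EPCAM",),
    "mesenchymal": ("VIM", "THY1"),
    "immune": ("PTPRC",),
}
DEFAULT_SUBTYPE_MARKERS: dict[str, tuple[str, ...]] = {
    "goblet": ("MUC2",),
    "enterocyte": ("CA2", "FABP1"),
    "stem_like": ("LGR5", "MKI67", "OLFM4"),
}

UNASSIGNED = "unassigned"


@dataclass
class MarkerSet:
    """Named marker gene lists with a fixed tie-break order."""

    types: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_MARKERS)
    )
    order: tuple[str, ...] = MAJOR_TYPE_ORDER

    def __post_init__(self) -> None:
        for name, genes in self.types.items():
            if not genes:
                raise ValueError(f"marker list for {name!r} is empty")
        self.order = tuple(t for t in self.order if t in self.types) + tuple(
            t for t in self.types if t not in self.order
        )


def log_expr(tpm: pd.DataFrame) -> pd.DataFrame:
    return np.log2(tpm + 1.0)


def filter_cells(
    tpm: pd.DataFrame,
    min_genes: int = 2000,
    min_top2_corr: float = 0.6,
) -> tuple[list[str], pd.DataFrame]:
    """Keep cells detecting > min_genes genes with 2nd-best correlation > min_top2_corr.

    Both thresholds are strict. The top-2 correlation of a cell is the
    second-largest Pearson correlation of its log2(TPM+1) profile against
    every other cell, computed on the full pre-filter population so that
    one bad cell cannot drag down its neighbours' statistics.

    Returns the kept cell ids and a per-cell diagnostics table
    (n_genes_detected, top2_corr, kept, reason).
    """
    if tpm.shape[1] < 3:
        raise ValueError("need at least 3 cells (top-2 correlation undefined)")
    detected = (tpm > 0).sum(axis=0)
    X = log_expr(tpm).to_numpy()
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(corr, -np.inf)
    corr = np.nan_to_num(corr, nan=-np.inf)  # zero-variance cells correlate with nothing
    top2 = np.sort(corr, axis=0)[-2, :]
    kept_mask = (detected.to_numpy() > min_genes) & (top2 > min_top2_corr)
    reasons = np.where(
        detected.to_numpy() <= min_genes,
        "low_gene_count",
        np.where(top2 <= min_top2_corr, "low_correlation", ""),
    )
    diag = pd.DataFrame(
        {
            "n_genes_detected": detected,
            "top2_corr": top2,
            "kept": kept_mask,
            "reason": reasons,
        },
        index=tpm.columns,
    )
    return list(tpm.columns[kept_mask]), diag


def mito_ratio(
    assigned_counts: pd.DataFrame, mito_genes: Iterable[str]
) -> tuple[pd.Series, float]:
    """Per-cell fraction of assigned reads mapping to mitochondrial genes.

    ``assigned_counts`` is a gene x cell read (or molecule) count table.
    Cells with zero assigned reads get NaN, flagged rather than dropped.
    Returns the per-cell fractions and their median over defined cells.
    """
    mito = [g for g in mito_genes if g in assigned_counts.index]
    totals = assigned_counts.sum(axis=0).astype(float)
    mito_sum = (
        assigned_counts.loc[mito].sum(axis=0).astype(float)
        if mito
        else pd.Series(0.0, index=assigned_counts.columns)
    )
    frac = mito_sum.where(totals > 0) / totals.where(totals > 0)
    return frac, float(frac.median())


def assign_types(
    tpm: pd.DataFrame,
    markers: Optional[MarkerSet] = None,
    subtype_markers: Optional[MarkerSet] = None,
) -> pd.DataFrame:
    """Marker-score cell typing.

    score(type, cell) = mean log2(TPM+1) over the type's marker genes;
    the label is the argmax, ties broken by the marker set's fixed order
    (epithelial > mesenchymal > immune by default). Cells scoring 0 for
    every type get the reserved label "unassigned". If ``subtype_markers``
    is given, epithelial cells are re-scored against the subtype panel.
    """
    markers = markers or MarkerSet()
    X = log_expr(tpm)
    scores = {}
    for tname in markers.order:
        genes = [g for g in markers.types[tname] if g in tpm.index]
        if not genes:
            raise ValueError(f"no marker of type {tname!r} present in the matrix")
        scores[tname] = X.loc[genes].mean(axis=0)
    score_df = pd.DataFrame(scores)[list(markers.order)]
    arr = score_df.to_numpy()
    labels = np.asarray(list(markers.order), dtype=object)[arr.argmax(axis=1)]
    labels = np.where(arr.max(axis=1) > 0, labels, UNASSIGNED)
    out = score_df.copy()
    out["label"] = labels
    if subtype_markers is not None:
        sub = assign_types(tpm, markers=subtype_markers)
        out["subtype"] = np.where(out["label"] == "epithelial", sub["label"], "")
    return out


def select_degs(
    tpm: pd.DataFrame,
    cells_a: Sequence[str],
    cells_b: Sequence[str],
    logfc_threshold: float = 1.5,
    min_pct: float = 0.25,
    min_diff_pct: float = 0.25,
) -> pd.DataFrame:
    """Genes specific to group A versus group B.

    pct_X is the expressed fraction (TPM > 0) in group X; the fold change
    is log2((mean TPM_A + 1) / (mean TPM_B + 1)). A gene is kept when
    pct_A >= min_pct, |pct_A - pct_B| >= min_diff_pct and
    logFC >= logfc_threshold. The symmetric call (B, A) yields the
    B-specific list; the two are disjoint by construction.
    """
    cells_a, cells_b = list(cells_a), list(cells_b)
    if not cells_a or not cells_b:
        raise ValueError("both cell groups must be non-empty")
    a, b = tpm[cells_a], tpm[cells_b]
    pct_a = (a > 0).mean(axis=1)
    pct_b = (b > 0).mean(axis=1)
    logfc = np.log2((a.mean(axis=1) + 1.0) / (b.mean(axis=1) + 1.0))
    table = pd.DataFrame({"logfc": logfc, "pct_a": pct_a, "pct_b": pct_b})
    keep = (
        (pct_a >= min_pct)
        & ((pct_a - pct_b).abs() >= min_diff_pct)
        & (logfc >= logfc_threshold)
    )
    return table[keep].sort_values("logfc", ascending=False)


def coexpression_fraction(
    tpm: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    groups: pd.Series,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-group fraction of cells co-expressing two genes above a TPM threshold.

    Mirrors the EPCAM/VIM partial-EMT readout: for each group, the share
    of cells with both genes above ``threshold``, plus the mean
    expression of each gene within its positive subpopulation (e.g. VIM
    level in VIM+ cells).
    """
    for g in (gene_a, gene_b):
        if g not in tpm.index:
            raise KeyError(f"gene {g!r} absent from matrix")
    ea, eb = tpm.loc[gene_a], tpm.loc[gene_b]
    both = (ea > threshold) & (eb > threshold)
    rows = {}
    for grp, cells in groups.groupby(groups).groups.items():
        cells = list(cells)
        pos_a = ea[cells] > threshold
        pos_b = eb[cells] > threshold
        rows[grp] = {
            "n_cells": len(cells),
            "frac_coexpressing": float(both[cells].mean()),
            f"mean_{gene_a}_in_{gene_a}_pos": float(ea[cells][pos_a].mean())
            if pos_a.any()
            else np.nan,
            f"mean_{gene_b}_in_{gene_b}_pos": float(eb[cells][pos_b].mean())
            if pos_b.any()
            else np.nan,
        }
    return pd.DataFrame(rows).T.rename_axis("group")


DEFAULT_BIN_EDGES = (0.0, 10.0, 100.0)


def expression_bins(
    tpm: pd.DataFrame,
    groups: pd.Series,
    gene: str = "MKI67",
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> tuple[pd.DataFrame, float]:
    """Per-group proportions of cells in expression bins, with a group test.

    Bins are {0}, (0, e1], (e1, e2], ..., (e_last, inf) over TPM (the
    first edge must be 0; zero expression is its own bin). Association
    between group and bin is tested by chi-square without continuity
    correction, falling back to Fisher's exact test for 2x2 tables with
    any expected count < 5.
    """
    if gene not in tpm.index:
        raise KeyError(f"gene {gene!r} absent from matrix")
    edges = list(bin_edges)
    if sorted(set(edges)) != edges:
        raise ValueError("bin edges must be strictly increasing")
    expr = tpm.loc[gene]
    if not edges:  # degenerate single bin covering everything
        binned = pd.Series(pd.Categorical(["[0,inf)"] * len(expr)), index=expr.index)
    else:
        if edges[0] != 0:
            raise ValueError("first bin edge must be 0")
        full_edges = edges + [np.inf]
        labels = ["0"] + [
            f"({full_edges[i]:g},{full_edges[i+1]:g}]" for i in range(len(full_edges) - 1)
        ]
        binned = pd.cut(expr, [-np.inf] + full_edges, labels=labels, right=True)
    tab = pd.crosstab(groups, binned)
    if (tab.sum(axis=1) == 0).any():
        raise ValueError("empty group in expression_bins")
    props = tab.div(tab.sum(axis=1), axis=0)
    counts = tab.loc[:, tab.sum(axis=0) > 0]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        p = 1.0
    else:
        chi2, p, dof, expected = stats.chi2_contingency(counts, correction=False)
        if counts.shape == (2, 2) and (expected < 5).any():
            p = float(stats.fisher_exact(counts)[1])
    return props, float(p)
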