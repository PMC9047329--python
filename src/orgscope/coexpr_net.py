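"""Tumor-specific gene co-expression network.

Nodes are tumor-specific genes; edges connect gene pairs whose Pearson
correlation across in-vivo tumor cells (on log2(TPM+1)) reaches a
threshold. Weakly connected vertices (degree < 3) are pruned
iteratively until a fixed point. Node colors carry the log2 fold change
of mean expression between two cell groups, so the same topology can be
painted with several group comparisons.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd


def build_network(
    tpm: pd.DataFrame,
    cells: Sequence[str],
    genes: Sequence[str],
    corr_threshold: float = 0.3,
    min_degree: int = 3,
    method: str = "pearson",
    iterative: bool = True,
) -> nx.Graph:
    """Correlation graph over genes, pruned to minimum degree.

    Pairwise gene-gene correlation is computed across ``cells`` on
    log2(TPM+1); an edge is retained iff correlation >= corr_threshold.
    Zero-variance genes are excluded with a warning. Vertices with
    degree < min_degree are then removed — iteratively by default, since
    each removal can drop a neighbour below the threshold; a single
    pass is available with ``iterative=False``.
    """
    genes = [g for g in genes if g in tpm.index]
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    cells = list(cells)
    if len(cells) < 3:
        raise ValueError("need at least 3 cells")
    X = np.log2(tpm.loc[genes, cells].to_numpy(dtype=float) + 1.0)
    var = X.var(axis=1)
    constant = var <= 1e-12
    if constant.any():
        dropped = [g for g, c in zip(genes, constant) if c]
        warnings.warn(f"excluding {len(dropped)} constant gene(s): {dropped[:5]}")
        genes = [g for g, c in zip(genes, constant) if not c]
        X = X[~constant]
    if method == "spearman":
        from scipy.stats import rankdata

        X = rankdata(X, axis=1)
    corr = np.corrcoef(X)
    g = nx.Graph()
    g.add_nodes_from(genes)
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = corr[iu, ju] >= corr_threshold
    g.add_weighted_edges_from(
        (genes[i], genes[j], float(corr[i, j]))
        for i, j in zip(iu[keep], ju[keep])
    )
    return prune_low_degree(g, min_degree=min_degree, iterative=iterative)


def prune_low_degree(g: nx.Graph, min_degree: int = 3, iterative: bool = True) -> nx.Graph:
    """Remove vertices with fewer than ``min_degree`` edges."""
    g = g.copy()
    while True:
        low = [n for n, d in g.degree() if d < min_degree]
        if not low:
            break
        g.remove_nodes_from(low)
        if not iterative:
            break
    return g


def color_nodes(
    g: nx.Graph,
    tpm: pd.DataFrame,
    cells_a: Sequence[str],
    cells_b: Sequence[str],
    attr: str = "color_value",
) -> nx.Graph:
    """Attach log2 fold change of group means as a node attribute.

    color_value(gene) = log2((mean TPM in A + 1) / (mean TPM in B + 1)).
    Typical comparisons paint tumor in vivo, tumor organoid and normal
    organoid epithelium each against normal in-vivo epithelium.
    """
    cells_a, cells_b = list(cells_a), list(cells_b)
    if not cells_a or not cells_b:
        raise ValueError("both groups must be non-empty")
    missing = [n for n in g.nodes if n not in tpm.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:5]}")
    mean_a = tpm.loc[list(g.nodes), cells_a].mean(axis=1)
    mean_b = tpm.loc[list(g.nodes), cells_b].mean(axis=1)
    fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    nx.set_node_attributes(g, fc.to_dict(), attr)
    return g


def to_edge_table(g: nx.Graph) -> pd.DataFrame:
    rows = [
        {"gene_a": a, "gene_b": b, "weight": d.get("weight", np.nan)}
        for a, b, d in g.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])
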