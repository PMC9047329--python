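"""Mitochondrial-mutation lineage tracing.

Mitochondrial DNA variants persist through cell division and serve as
endogenous barcodes of clonal ancestry: sites mutant in tumor cells but
wild-type in matched normal cells mark the tumor lineage, and the
pattern of such sites carried by each cell assigns it to a clone. The
module consumes a per-cell per-site pileup (depth, alt-read count);
variant calling from alignments is upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MUTANT = "mutant"
WILD_TYPE = "wild_type"
LOW_COVERAGE = "low_coverage"

WT_LABEL = "wild-type"
UNASSIGNABLE = "unassignable"


def classify_site(
    depth: int, alt: int, min_depth: int = 9, min_vaf: float = 0.2
) -> str:
    """Three-state call for one cell at one mitochondrial site.

    Sites covered by fewer than ``min_depth`` reads (default: fewer than
    9) are uncallable (low_coverage); otherwise the site is mutant when
    the variant allele fraction alt/depth reaches ``min_vaf``, else
    wild-type.
    """
    if alt > depth or alt < 0 or depth < 0:
        raise ValueError(f"bad pileup counts depth={depth} alt={alt}")
    if depth < min_depth:
        return LOW_COVERAGE
    return MUTANT if alt / depth >= min_vaf else WILD_TYPE


def classify_table(
    pileup: pd.DataFrame, min_depth: int = 9, min_vaf: float = 0.2
) -> pd.DataFrame:
    """Vectorized classify_site over a (cell, site, depth, alt) table."""
    depth = pileup["depth"].to_numpy()
    alt = pileup["alt"].to_numpy()
    if (alt > depth).any() or (alt < 0).any() or (depth < 0).any():
        raise ValueError("pileup contains alt > depth or negative counts")
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    state = np.where(
        depth < min_depth, LOW_COVERAGE, np.where(vaf >= min_vaf, MUTANT, WILD_TYPE)
    )
    out = pileup.copy()
    out["state"] = state
    return out


def state_matrix(calls: pd.DataFrame) -> pd.DataFrame:
    """Cells x sites matrix of three-state calls."""
    return calls.pivot(index="cell", columns="site", values="state")


def find_specific_sites(
    calls: pd.DataFrame,
    tumor_cells: Sequence[str],
    normal_cells: Sequence[str],
    min_pct_tumor: float = 0.2,
    max_pct_normal: float = 0.05,
) -> pd.DataFrame:
    """Tumor-specific mitochondrial sites.

    Among callable (not low-coverage) cells, a site qualifies when the
    mutant fraction is at least ``min_pct_tumor`` in tumor cells and at
    most ``max_pct_normal`` in normal cells. Sites callable in no tumor
    cell are excluded with a warning column rather than an error.
    """
    tumor_cells, normal_cells = set(tumor_cells), set(normal_cells)
    if not tumor_cells or not normal_cells:
        raise ValueError("both tumor and normal cell groups are required")
    if "state" not in calls.columns:
        calls = classify_table(calls)
    rows = []
    for site, sub in calls.groupby("site"):
        t = sub[sub["cell"].isin(tumor_cells) & (sub["state"] != LOW_COVERAGE)]
        n = sub[sub["cell"].isin(normal_cells) & (sub["state"] != LOW_COVERAGE)]
        if len(t) == 0:
            import warnings

            warnings.warn(f"site {site}: callable in no tumor cell, excluded")
            continue
        pct_t = (t["state"] == MUTANT).mean()
        pct_n = (n["state"] == MUTANT).mean() if len(n) else 0.0
        rows.append(
            {
                "site": site,
                "pct_mutant_tumor": pct_t,
                "pct_mutant_normal": pct_n,
                "n_callable_tumor": len(t),
                "n_callable_normal": len(n),
                "specific": pct_t >= min_pct_tumor and pct_n <= max_pct_normal,
            }
        )
    return pd.DataFrame(rows).set_index("site")


@dataclass
class CloneAssignment:
    labels: pd.Series  # cell id -> clone label
    site_table: pd.DataFrame  # per-site specificity diagnostics
    patterns: dict[str, frozenset]  # clone label -> mutant-site set


def assign_clones(
    calls: pd.DataFrame, sites: Sequence[str]
) -> CloneAssignment:
    """Assign each cell a lineage label from its tumor-specific-site pattern.

    Per cell, over its callable tumor-specific sites: mutant at at least
    half of them assigns a tumor clone whose identity is the exact set
    of mutant sites (the site-pattern key); mutant at none is wild-type;
    no callable site is unassignable. Cells whose callable sites are a
    strict subset of the panel are matched to the nearest fully-observed
    clone pattern by Hamming distance on callable sites; ties go to
    unassignable. Invariant to cell and site order.
    """
    sites = sorted(set(sites))
    if not sites:
        raise ValueError("sites must be non-empty")
    if "state" not in calls.columns:
        calls = classify_table(calls)
    sub = calls[calls["site"].isin(sites)]
    mat = sub.pivot(index="cell", columns="site", values="state").reindex(
        columns=sites
    )

    # clone patterns observed in fully-callable cells, in deterministic order
    full_patterns: list[frozenset] = []
    cell_info = {}
    for cell in sorted(mat.index):
        row = mat.loc[cell]
        callable_sites = [s for s in sites if row[s] in (MUTANT, WILD_TYPE)]
        mutant_sites = frozenset(s for s in callable_sites if row[s] == MUTANT)
        cell_info[cell] = (callable_sites, mutant_sites)
        if len(callable_sites) == len(sites) and mutant_sites:
            if len(mutant_sites) >= len(callable_sites) / 2:
                if mutant_sites not in full_patterns:
                    full_patterns.append(mutant_sites)
    pattern_label = {
        pat: f"tumor-clone-{i+1}:" + "+".join(sorted(pat))
        for i, pat in enumerate(sorted(full_patterns, key=lambda p: sorted(p)))
    }

    labels = {}
    for cell, (callable_sites, mutant_sites) in cell_info.items():
        if not callable_sites:
            labels[cell] = UNASSIGNABLE
        elif not mutant_sites:
            labels[cell] = WT_LABEL
        elif len(mutant_sites) >= len(callable_sites) / 2:
            if len(callable_sites) == len(sites):
                labels[cell] = pattern_label.get(
                    mutant_sites,
                    "tumor-clone:" + "+".join(sorted(mutant_sites)),
                )
            else:
                # partial pattern: nearest full clone pattern on callable sites
                best, best_d, tie = None, None, False
                for pat, lab in pattern_label.items():
                    d = sum(
                        1
                        for s in callable_sites
                        if (s in pat) != (s in mutant_sites)
                    )
                    if best_d is None or d < best_d:
                        best, best_d, tie = lab, d, False
                    elif d == best_d:
                        tie = True
                labels[cell] = UNASSIGNABLE if (best is None or tie) else best
        else:
            labels[cell] = WT_LABEL

    label_series = pd.Series(labels, name="clone").rename_axis("cell").sort_index()
    site_tab = (
        sub.assign(is_mutant=lambda d: d["state"] == MUTANT)
        .groupby("site")["is_mutant"]
        .mean()
        .to_frame("pct_mutant")
    )
    return CloneAssignment(
        labels=label_series,
        site_table=site_tab,
        patterns={lab: pat for pat, lab in pattern_label.items()},
    )
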