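"""Shared data containers used across the pipeline stages.

Conventions
-----------
* Genomic coordinates are 0-based, half-open everywhere.
* Expression matrices are gene x cell DataFrames; the gene annotation
  (chromosome, start, within-chromosome ordinal) travels alongside.
* Mitochondrial sites are keyed as ``"<position>_<alt-base>"`` strings,
  e.g. ``"6719_G"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

TPM_TOTAL = 1_000_000.0

#: fixed genomic bin width shared by expression-CNV aggregation and WGS
#: depth ratios (10 Mb)
WINDOW_BP = 10_000_000


@dataclass(frozen=True)
class CellRecord:
    """Identity and provenance of a single cell.

    ``medium`` and ``term`` are ``"none"`` for cells sampled directly from
    tissue (``source == "invivo"``); organoid cells carry the culture
    medium (chemical-defined or conditioned) and culture term.
    """

    cell_id: str
    patient: str
    tissue: str  # "tumor" | "normal"
    source: str  # "invivo" | "organoid"
    medium: str = "none"  # "chem" | "cond" | "none"
    term: str = "none"  # "short" | "long" | "none"
    passage: Optional[int] = None

    def __post_init__(self) -> None:
        if self.tissue not in ("tumor", "normal"):
            raise ValueError(f"bad tissue {self.tissue!r}")
        if self.source not in ("invivo", "organoid"):
            raise ValueError(f"bad source {self.source!r}")
        if (self.medium == "none") != (self.source == "invivo"):
            raise ValueError(
                "medium must be 'none' exactly for in-vivo cells "
                f"(got source={self.source!r}, medium={self.medium!r})"
            )

    def matches(self, selector: Mapping[str, object]) -> bool:
        """True if every key of ``selector`` equals this record's field.

        Selector values may also be a list/tuple/set of admissible values.
        Used to express carrier predicates (CNV segments, mito clones)
        in plain serializable form.
        """
        for key, want in selector.items():
            have = getattr(self, key)
            if isinstance(want, (list, tuple, set, frozenset)):
                if have not in want:
                    return False
            elif have != want:
                return False
        return True


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    """Cell metadata table indexed by cell id."""
    df = pd.DataFrame(
        {
            "patient": [r.patient for r in records],
            "tissue": [r.tissue for r in records],
            "source": [r.source for r in records],
            "medium": [r.medium for r in records],
            "term": [r.term for r in records],
        },
        index=pd.Index([r.cell_id for r in records], name="cell"),
    )
    return df


def make_gene_track(
    gene_ids: list[str], chroms: list[str], starts: list[int]
) -> pd.DataFrame:
    """Gene annotation table: chromosome, start (bp), within-chromosome ordinal.

    Genes are sorted by (chromosome, start); ordinals are dense per
    chromosome and strictly increasing in start.
    """
    track = pd.DataFrame(
        {"chrom": chroms, "start": starts},
        index=pd.Index(gene_ids, name="gene"),
    )
    track = track.sort_values(["chrom", "start"], kind="stable")
    track["ordinal"] = track.groupby("chrom").cumcount()
    return track


@dataclass
class ExpressionMatrix:
    """Gene x cell UMI counts with gene annotation and TPM.

    ``counts`` rows are ordered like ``genes`` (sorted by chromosome and
    start). ``tpm`` is computed once from counts: each nonzero cell column
    sums to 1e6.
    """

    counts: pd.DataFrame
    genes: pd.DataFrame
    cells: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    tpm: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.genes.index):
            self.counts = self.counts.reindex(self.genes.index, fill_value=0)
        if self.tpm is None:
            from .strt_reads import tpm_normalize

            self.tpm = tpm_normalize(self.counts)
        if self.cells is None:
            self.cells = pd.DataFrame(index=self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, cell_ids) -> "ExpressionMatrix":
        cell_ids = list(cell_ids)
        return ExpressionMatrix(
            counts=self.counts[cell_ids],
            genes=self.genes,
            cells=self.cells.loc[cell_ids],
            tpm=self.tpm[cell_ids],
        )


def genomic_window_index(start_bp: np.ndarray, window_bp: int = WINDOW_BP) -> np.ndarray:
    """Window ordinal containing each position (floor division)."""
    return np.asarray(start_bp, dtype=np.int64) // int(window_bp)


def window_label(chrom: str, widx: int, window_bp: int = WINDOW_BP) -> str:
    return f"{chrom}:{widx * window_bp}-{(widx + 1) * window_bp}"
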