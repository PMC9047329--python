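"""STRT read demultiplexing, read QC, UMI counting and TPM normalization.

The STRT library layout puts the cell barcode in bases 0-8 of read 2 and
the unique molecular identifier (UMI) in bases 8-16 (0-based, half-open);
read 1 carries the cDNA fragment. Reads are demultiplexed by exact barcode
match, quality-filtered, assigned to genes, deduplicated by UMI per gene
and cell, and normalized to transcripts-per-million (TPM).
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

BARCODE_LEN = 8
UMI_LEN = 8

_GENE_TAG = re.compile(r"gene=([^\s;]+)")


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read: R1 = cDNA, R2 = barcode + UMI."""

    read_name: str
    r1_seq: str
    r1_qual: str
    r2_seq: str

    def __post_init__(self) -> None:
        if len(self.r1_seq) != len(self.r1_qual):
            raise ValueError(f"{self.read_name}: R1 sequence/quality length mismatch")


@dataclass(frozen=True)
class AssignedRead:
    """A read routed to a cell, with UMI and (optional) gene of origin."""

    barcode: str
    umi: str
    gene: Optional[str]
    trimmed_len: int


@dataclass
class DemuxResult:
    by_barcode: dict[str, list[ReadPair]]
    unassigned: int
    unassigned_reasons: Counter

    @property
    def assigned(self) -> int:
        return sum(len(v) for v in self.by_barcode.values())


def split_barcodes(reads: Iterable[ReadPair], whitelist: Iterable[str]) -> DemuxResult:
    """Demultiplex read pairs by the 8-nt cell barcode at R2[0:8].

    Exact match against the whitelist only — no error correction. Reads
    whose barcode is not whitelisted, or whose R2 is shorter than 16 nt
    (no room for barcode + UMI), are tallied as unassigned with a reason.
    """
    wl = set(whitelist)
    if not wl:
        raise ValueError("whitelist is empty")
    bad = [b for b in wl if len(b) != BARCODE_LEN]
    if bad:
        raise ValueError(f"whitelist entries must be {BARCODE_LEN}-mers: {bad[:3]}")

    by_barcode: dict[str, list[ReadPair]] = defaultdict(list)
    reasons: Counter = Counter()
    unassigned = 0
    for rp in reads:
        if len(rp.r2_seq) < BARCODE_LEN + UMI_LEN:
            unassigned += 1
            reasons["r2_too_short"] += 1
            continue
        bc = rp.r2_seq[:BARCODE_LEN]
        if bc not in wl:
            unassigned += 1
            reasons["unknown_barcode"] += 1
            continue
        by_barcode[bc].append(rp)
    return DemuxResult(dict(by_barcode), unassigned, reasons)


def extract_umi(rp: ReadPair) -> str:
    return rp.r2_seq[BARCODE_LEN : BARCODE_LEN + UMI_LEN]


def trim_polya(seq: str, qual: str, min_len: int = 6, min_a_frac: float = 0.9) -> tuple[str, str]:
    """Trim the 3' poly-A tail: remove the longest suffix of length >=
    ``min_len`` whose A-fraction is >= ``min_a_frac``.

    The A-fraction tolerance absorbs isolated sequencing errors inside
    the tail. Removing the longest qualifying suffix is idempotent: any
    qualifying suffix of the remainder would have extended the removed one.
    """
    n = len(seq)
    cut = n  # index where the removed suffix starts; n = nothing removed
    n_a = 0
    # walk from the 3' end; suffix starting at i has length n - i
    for i in range(n - 1, -1, -1):
        if seq[i] == "A":
            n_a += 1
        length = n - i
        if length >= min_len and n_a / length >= min_a_frac:
            cut = i
    return seq[:cut], qual[:cut]


def qc_read(
    r1_seq: str,
    r1_qual: str,
    min_len: int = 40,
    min_qual: int = 38,
    min_qual_frac: float = 0.5,
    max_n_frac: float = 0.10,
) -> tuple[bool, str, str]:
    """Read-level QC after poly-A trimming.

    A read passes iff, evaluated on the trimmed sequence, it is
    (1) at least ``min_len`` bp long, (2) more than ``min_qual_frac`` of
    bases have Phred quality strictly greater than ``min_qual``, and
    (3) strictly less than ``max_n_frac`` of bases are N. Boundary cases
    fail: exactly half high-quality bases fails (2); an N fraction of
    exactly 0.10 fails (3); length exactly 40 passes (1).

    Returns ``(passed, trimmed_seq, reason)`` with reason one of
    ``"", "length", "quality", "n_content"``.
    """
    quals = np.frombuffer(r1_qual.encode("ascii"), dtype=np.uint8).astype(int) - 33
    if quals.size and (quals.min() < 0 or quals.max() > 60):
        raise ValueError("qualities are not phred33")
    seq, qual = trim_polya(r1_seq, r1_qual)
    if len(seq) < min_len:
        return False, seq, "length"
    q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(int) - 33
    if (q > min_qual).mean() <= min_qual_frac:
        return False, seq, "quality"
    n_frac = seq.count("N") / len(seq)
    if n_frac >= max_n_frac:
        return False, seq, "n_content"
    return True, seq, ""


def gene_from_name(read_name: str) -> Optional[str]:
    """Gene-of-origin tag carried in a read name (``gene=<id>``), or None.

    This is the alignment surrogate: synthetic reads carry their source
    gene in the name so quantification is testable without an aligner.
    An external read -> gene TSV may be used instead (see assign_genes).
    """
    m = _GENE_TAG.search(read_name)
    return m.group(1) if m else None


def assign_genes(
    demux: DemuxResult,
    read_gene_map: Optional[Mapping[str, str]] = None,
    apply_qc: bool = True,
    **qc_params,
) -> tuple[list[AssignedRead], pd.DataFrame]:
    """QC demultiplexed reads and attach gene assignments.

    Genes come either from an explicit read-name -> gene map or from the
    ``gene=`` tag in the read name. Returns the assigned-read stream and
    a per-fate count table (for the run report).
    """
    out: list[AssignedRead] = []
    fates: Counter = Counter()
    for bc, rps in demux.by_barcode.items():
        for rp in rps:
            if apply_qc:
                ok, trimmed, reason = qc_read(rp.r1_seq, rp.r1_qual, **qc_params)
                if not ok:
                    fates[f"fail_{reason}"] += 1
                    continue
            else:
                trimmed = rp.r1_seq
            gene = (
                read_gene_map.get(rp.read_name)
                if read_gene_map is not None
                else gene_from_name(rp.read_name)
            )
            fates["pass_assigned" if gene else "pass_unassigned_gene"] += 1
            out.append(AssignedRead(bc, extract_umi(rp), gene, len(trimmed)))
    fates["unassigned_barcode"] = demux.unassigned
    table = pd.DataFrame(
        {"count": pd.Series(fates, dtype=int)}
    ).rename_axis("fate")
    return out, table


def count_umis(
    assigned: Iterable[AssignedRead],
    genes: Optional[list[str]] = None,
    cells: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Molecule counts: distinct UMI sequences per (gene, cell).

    Reads sharing a UMI within one gene and cell are PCR duplicates and
    collapse to a single molecule; reads without a gene assignment are
    ignored. Gene/cell universes may be given to fix the output shape.
    """
    seen: dict[tuple[str, str], set] = defaultdict(set)
    for ar in assigned:
        if ar.gene is None:
            continue
        seen[(ar.gene, ar.barcode)].add(ar.umi)
    gene_ids = genes if genes is not None else sorted({g for g, _ in seen})
    cell_ids = cells if cells is not None else sorted({c for _, c in seen})
    counts = pd.DataFrame(
        0, index=pd.Index(gene_ids, name="gene"), columns=pd.Index(cell_ids, name="cell")
    )
    for (g, c), umis in seen.items():
        if g in counts.index and c in counts.columns:
            counts.loc[g, c] = len(umis)
    return counts


def tpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Transcripts per million: each cell's counts scaled to sum to 1e6.

    Cells with zero total stay all-zero.
    """
    arr = counts.to_numpy(dtype=float)
    totals = arr.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = np.where(totals > 0, arr / totals * 1e6, 0.0)
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)
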