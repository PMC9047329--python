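"""Readers and writers for the pipeline's on-disk formats.

Plain-text formats throughout: FASTQ (phred33) for reads, MatrixMarket
(.mtx) plus genes/barcodes TSV for count matrices, TSV for tables, YAML
for configs, JSON for run reports. Coordinates in all genomic tables
are 0-based, half-open.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .strt_reads import ReadPair


def write_fastq_pairs(pairs: Iterable[ReadPair], r1_path, r2_path) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for rp in pairs:
            f1.write(f"@{rp.read_name}\n{rp.r1_seq}\n+\n{rp.r1_qual}\n")
            f2.write(f"@{rp.read_name}\n{rp.r2_seq}\n+\n{'I' * len(rp.r2_seq)}\n")


def read_fastq_pairs(r1_path, r2_path) -> list[ReadPair]:
    def records(path):
        with open(path) as fh:
            while True:
                name = fh.readline().strip()
                if not name:
                    return
                seq = fh.readline().strip()
                fh.readline()
                qual = fh.readline().strip()
                yield name[1:], seq, qual

    out = []
    for (n1, s1, q1), (n2, s2, _q2) in zip(records(r1_path), records(r2_path)):
        if n1.split()[0] != n2.split()[0]:
            raise ValueError(f"R1/R2 out of sync: {n1} vs {n2}")
        out.append(ReadPair(read_name=n1, r1_seq=s1, r1_qual=q1, r2_seq=s2))
    return out


def write_counts_mtx(counts: pd.DataFrame, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = scipy.sparse.csr_matrix(counts.to_numpy())
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), mat)
    counts.index.to_series().to_csv(outdir / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(counts.columns).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_counts_mtx(indir) -> pd.DataFrame:
    indir = Path(indir)
    mat = scipy.io.mmread(str(indir / "matrix.mtx")).toarray().astype(np.int64)
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0]
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    return pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=list(cells))


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_gene_track_bed(track: pd.DataFrame, path) -> None:
    """BED-like gene track: chrom, start, gene (tab-separated, no header)."""
    out = track.reset_index()[["chrom", "start", "gene"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_gene_track_bed(path) -> pd.DataFrame:
    from .containers import make_gene_track

    raw = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "gene"])
    return make_gene_track(list(raw["gene"]), list(raw["chrom"]), list(raw["start"]))


def write_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.ndarray,)):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
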