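"""End-to-end orchestration: simulate → demux → quantify → QC → annotate →
CNV → mito lineage → network → WGS windows, from one config with one seed.

The single run seed fans out to per-stage seeds by fixed offsets (the
same derivation the simulator uses), so any stage re-run in isolation
reproduces its part of a full run. Re-running the whole pipeline with
an identical config produces byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import cell_qc, cnv_expr, coexpr_net, io, mito_lineage, strt_reads, wgs_windows
from .containers import ExpressionMatrix
from .synthdata import (
    CnvSegment,
    GroupSpec,
    MitoClone,
    Program,
    TruthConfig,
    generate_population,
    simulate_mito_pileup,
    simulate_wgs_windows,
    synthesize_reads,
)

ALL_STAGES = (
    "simulate",
    "reads",
    "quantify",
    "qc",
    "annotate",
    "signatures",
    "degs",
    "network",
    "cnv",
    "mito",
    "wgs",
)


@dataclass
class RunConfig:
    """One config for a full pipeline run; unknown keys are rejected."""

    seed: int = 0
    outdir: str = "orgscope_run"
    stages: tuple[str, ...] = ALL_STAGES
    small_cohort: bool = True  # use the desk-scale simulator preset
    truth_overrides: Mapping[str, object] = field(default_factory=dict)
    fail_fraction: float = 0.05
    qc: Mapping[str, object] = field(
        default_factory=lambda: {"min_genes": 2000, "min_top2_corr": 0.6}
    )
    degs: Mapping[str, object] = field(
        default_factory=lambda: {
            "logfc_threshold": 1.5,
            "min_pct": 0.25,
            "min_diff_pct": 0.25,
        }
    )
    cnv: Mapping[str, object] = field(
        default_factory=lambda: {"min_avg_rel_expr": 1.5, "k": 100}
    )
    mito: Mapping[str, object] = field(
        default_factory=lambda: {
            "min_depth": 9,
            "min_vaf": 0.2,
            "min_pct_tumor": 0.2,
            "max_pct_normal": 0.05,
        }
    )
    network: Mapping[str, object] = field(
        default_factory=lambda: {"corr_threshold": 0.3, "min_degree": 3}
    )

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "stages" in d:
            bad = set(d["stages"]) - set(ALL_STAGES)
            if bad:
                raise ValueError(f"unknown stages: {sorted(bad)}")
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(io.read_yaml(path) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def build_truth_config(config: RunConfig) -> TruthConfig:
    base = TruthConfig(seed=config.seed)
    if config.small_cohort:
        base = base.small()
    overrides = dict(config.truth_overrides)
    overrides.setdefault("seed", config.seed)
    known = {f.name for f in dataclasses.fields(TruthConfig)}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown truth config keys: {sorted(unknown)}")
    if "groups" in overrides:
        overrides["groups"] = tuple(
            GroupSpec(**g) if isinstance(g, dict) else g for g in overrides["groups"]
        )
    if "cnv_segments" in overrides:
        overrides["cnv_segments"] = tuple(
            CnvSegment(**s) if isinstance(s, dict) else s
            for s in overrides["cnv_segments"]
        )
    if "mito_clones" in overrides:
        overrides["mito_clones"] = tuple(
            MitoClone(**{**c, "sites": tuple(c["sites"])}) if isinstance(c, dict) else c
            for c in overrides["mito_clones"]
        )
    if "extra_programs" in overrides:
        overrides["extra_programs"] = tuple(
            Program(**{**p, "genes": tuple(p["genes"])}) if isinstance(p, dict) else p
            for p in overrides["extra_programs"]
        )
    if "genome" in overrides:
        overrides["genome"] = tuple(tuple(g) for g in overrides["genome"])
    return dataclasses.replace(base, **overrides)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the run report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": {}}
    enabled = [s for s in ALL_STAGES if s in config.stages]

    truth = matrix = None
    kept_cells: Optional[list[str]] = None

    def need_population():
        nonlocal truth, matrix
        if truth is None:
            tc = build_truth_config(config)
            truth, matrix = generate_population(tc)
        return truth, matrix

    if "simulate" in enabled:
        truth, matrix = need_population()
        io.write_counts_mtx(matrix.counts, out / "counts")
        io.write_tsv(truth.cells, out / "cells.tsv")
        io.write_gene_track_bed(truth.genes, out / "genes.bed")
        report["stages"]["simulate"] = {
            "n_cells": int(matrix.n_cells),
            "n_genes": int(matrix.n_genes),
            "total_umis": int(matrix.counts.to_numpy().sum()),
        }

    if "reads" in enabled:
        truth, matrix = need_population()
        pairs = synthesize_reads(truth, matrix.counts, fail_fraction=config.fail_fraction)
        io.write_fastq_pairs(pairs, out / "reads_R1.fastq", out / "reads_R2.fastq")
        n_fail = sum(1 for p in pairs if ";fail=" in p.read_name)
        report["stages"]["reads"] = {
            "n_pairs": len(pairs),
            "n_injected_failing": n_fail,
            "n_molecules": len(pairs) - n_fail,
        }

    if "quantify" in enabled:
        truth, matrix = need_population()
        pairs = io.read_fastq_pairs(out / "reads_R1.fastq", out / "reads_R2.fastq")
        demux = strt_reads.split_barcodes(pairs, set(truth.barcodes.values()))
        assigned, fates = strt_reads.assign_genes(demux)
        bc_to_cell = {b: c for c, b in truth.barcodes.items()}
        assigned = [
            dataclasses.replace(a, barcode=bc_to_cell[a.barcode]) for a in assigned
        ]
        counts = strt_reads.count_umis(
            assigned, genes=list(matrix.counts.index), cells=list(matrix.counts.columns)
        )
        io.write_counts_mtx(counts, out / "counts_recovered")
        io.write_tsv(fates, out / "read_fates.tsv")
        report["stages"]["quantify"] = {
            "reads_in": len(pairs),
            "reads_assigned": demux.assigned,
            "reads_unassigned": demux.unassigned,
            "recovered_equals_truth": bool(
                counts.to_numpy().sum() > 0
                and (counts.to_numpy() == matrix.counts.to_numpy()).all()
            ),
        }

    if "qc" in enabled:
        truth, matrix = need_population()
        kept_cells, diag = cell_qc.filter_cells(matrix.tpm, **config.qc)
        io.write_tsv(diag, out / "cell_qc.tsv")
        mito_genes = list(truth.genes.index[truth.genes["chrom"] == "chrM"])
        frac, med = cell_qc.mito_ratio(matrix.counts, mito_genes)
        io.write_tsv(frac.to_frame("mito_fraction"), out / "mito_fraction.tsv")
        report["stages"]["qc"] = {
            "cells_in": int(matrix.n_cells),
            "cells_kept": len(kept_cells),
            "median_mito_ratio": med,
        }

    def qc_cells():
        nonlocal kept_cells
        if kept_cells is None:
            truth, matrix = need_population()
            kept_cells, _ = cell_qc.filter_cells(matrix.tpm, **config.qc)
        return kept_cells

    if "annotate" in enabled:
        truth, matrix = need_population()
        cells = qc_cells()
        sub = matrix.tpm[cells] if cells else matrix.tpm
        types = cell_qc.assign_types(
            sub,
            markers=cell_qc.MarkerSet(),
            subtype_markers=cell_qc.MarkerSet(
                types=dict(cell_qc.DEFAULT_SUBTYPE_MARKERS),
                order=tuple(cell_qc.DEFAULT_SUBTYPE_MARKERS),
            ),
        )
        io.write_tsv(types, out / "cell_types.tsv")
        truth_types = truth.cells.loc[types.index, "cell_type"]
        acc = float((types["label"] == truth_types).mean()) if len(types) else float("nan")
        report["stages"]["annotate"] = {
            "cells_typed": int(len(types)),
            "accuracy_vs_truth": acc,
        }

    if "signatures" in enabled:
        truth, matrix = need_population()
        cells = qc_cells() or list(matrix.tpm.columns)
        sub = matrix.tpm[cells]
        groups = (
            truth.cells.loc[cells, "tissue"] + "_" + truth.cells.loc[cells, "source"]
        )
        coexp = cell_qc.coexpression_fraction(sub, "EPCAM", "VIM", groups)
        io.write_tsv(coexp, out / "epcam_vim_coexpression.tsv")
        props, p = cell_qc.expression_bins(sub, groups, gene="MKI67")
        io.write_tsv(props, out / "mki67_bins.tsv")
        report["stages"]["signatures"] = {
            "groups": int(len(coexp)),
            "mki67_bin_pvalue": p,
        }

    if "degs" in enabled:
        truth, matrix = need_population()
        cells = qc_cells() or list(matrix.tpm.columns)
        meta = truth.cells.loc[cells]
        a = list(meta.index[(meta["tissue"] == "tumor") & (meta["source"] == "invivo")])
        b = list(meta.index[(meta["tissue"] == "normal") & (meta["source"] == "invivo")])
        if a and b:
            degs = cell_qc.select_degs(matrix.tpm[cells], a, b, **config.degs)
            io.write_tsv(degs, out / "tumor_specific_genes.tsv")
            report["stages"]["degs"] = {"n_genes_selected": int(len(degs))}
        else:
            report["stages"]["degs"] = {"n_genes_selected": 0, "note": "missing group"}

    if "network" in enabled:
        truth, matrix = need_population()
        cells = qc_cells() or list(matrix.tpm.columns)
        meta = truth.cells.loc[cells]
        tumor_invivo = list(
            meta.index[(meta["tissue"] == "tumor") & (meta["source"] == "invivo")]
        )
        deg_path = out / "tumor_specific_genes.tsv"
        genes = (
            list(io.read_tsv(deg_path, index_col=0).index) if deg_path.exists() else []
        )
        if len(genes) >= 2 and len(tumor_invivo) >= 3:
            g = coexpr_net.build_network(
                matrix.tpm, tumor_invivo, genes, **config.network
            )
            normal_invivo = list(
                meta.index[(meta["tissue"] == "normal") & (meta["source"] == "invivo")]
            )
            if g.number_of_nodes() and normal_invivo:
                g = coexpr_net.color_nodes(g, matrix.tpm, tumor_invivo, normal_invivo)
            io.write_tsv(coexpr_net.to_edge_table(g), out / "network_edges.tsv", index=False)
            report["stages"]["network"] = {
                "n_nodes": g.number_of_nodes(),
                "n_edges": g.number_of_edges(),
            }
        else:
            report["stages"]["network"] = {"n_nodes": 0, "n_edges": 0, "note": "too few inputs"}

    if "cnv" in enabled:
        truth, matrix = need_population()
        cells = qc_cells()
        if not cells:
            report["stages"]["cnv"] = {"cells_in": 0, "n_windows": 0, "note": "no QC-passed cells"}
        else:
            profile, _scores = cnv_expr.cnv_profile(
                matrix.tpm[cells], truth.genes, **config.cnv
            )
            io.write_tsv(profile, out / "cnv_profile.tsv")
            report["stages"]["cnv"] = {
                "cells_in": len(cells),
                "n_windows": int(profile.shape[0]),
            }

    if "mito" in enabled:
        truth, matrix = need_population()
        pileup = simulate_mito_pileup(truth)
        calls = mito_lineage.classify_table(
            pileup,
            min_depth=config.mito["min_depth"],
            min_vaf=config.mito["min_vaf"],
        )
        meta = truth.cells
        tumor = list(meta.index[(meta["tissue"] == "tumor") & (meta["source"] == "invivo")])
        normal = list(meta.index[(meta["tissue"] == "normal") & (meta["source"] == "invivo")])
        site_tab = mito_lineage.find_specific_sites(
            calls,
            tumor,
            normal,
            min_pct_tumor=config.mito["min_pct_tumor"],
            max_pct_normal=config.mito["max_pct_normal"],
        )
        specific = list(site_tab.index[site_tab["specific"]])
        io.write_tsv(site_tab, out / "mito_sites.tsv")
        if specific:
            assignment = mito_lineage.assign_clones(calls, specific)
            io.write_tsv(assignment.labels.to_frame(), out / "mito_clones.tsv")
            n_tumor_clone = int(
                assignment.labels.str.startswith("tumor-clone").sum()
            )
        else:
            n_tumor_clone = 0
        report["stages"]["mito"] = {
            "n_sites_tested": int(len(site_tab)),
            "n_specific_sites": len(specific),
            "n_tumor_clone_cells": n_tumor_clone,
        }

    if "wgs" in enabled:
        truth, matrix = need_population()
        raw = simulate_wgs_windows(truth)
        table = wgs_windows.normalize_windows(raw)
        io.write_tsv(table, out / "wgs_cnv.tsv", index=False)
        report["stages"]["wgs"] = {
            "n_samples": int(raw.shape[1]),
            "n_windows": int(raw.shape[0]),
        }

    # cross-stage consistency
    if "qc" in report["stages"] and "cnv" in report["stages"]:
        assert (
            report["stages"]["cnv"]["cells_in"] == report["stages"]["qc"]["cells_kept"]
        ), "cells entering CNV must equal cells kept by QC"

    io.write_json(report, out / "run_report.json")
    return report
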