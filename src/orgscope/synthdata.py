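"""Ground-truth simulator for every pipeline input.

Emulates the study design of a patient-derived colorectal organoid
cohort: per patient, tumor and adjacent-normal cells sampled in vivo and
after organoid culture in two media (chemical-defined, conditioned) at
short and long term. From one explicit probabilistic model it produces

* a gene x cell UMI count matrix (negative-binomial with library-size
  variation, marker programs, CNV segments and dropout) plus TPM,
* STRT-style paired reads (R2 = barcode + UMI) with optional injected
  failing reads,
* a per-cell mitochondrial pileup (depth/alt counts) driven by planted
  clones,
* per-sample windowed WGS read counts driven by planted copy ratios,

together with the truth labels needed to score every downstream stage.

All randomness flows through one ``numpy.random.Generator`` seeded from
``TruthConfig.seed``; a fixed config reproduces identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import (
    WINDOW_BP,
    CellRecord,
    ExpressionMatrix,
    genomic_window_index,
    make_gene_track,
    records_to_frame,
)
from .strt_reads import ReadPair, tpm_normalize

# canonical marker genes placed into every synthetic gene universe
MAJOR_MARKERS = {
    "epithelial": ["EPCAM"],
    "mesenchymal": ["VIM", "THY1"],
    "immune": ["PTPRC"],
}
SUBTYPE_MARKERS = {
    "goblet": ["MUC2"],
    "enterocyte": ["CA2", "FABP1"],
    "stem_like": ["LGR5", "MKI67", "OLFM4"],
}
NAMED_GENES = [g for ms in (*MAJOR_MARKERS.values(), *SUBTYPE_MARKERS.values()) for g in ms]


@dataclass(frozen=True)
class GroupSpec:
    """One experimental arm: tissue x source x culture medium x term."""

    tissue: str
    source: str
    medium: str = "none"
    term: str = "none"


@dataclass(frozen=True)
class Program:
    """An expression program: a gene set elevated in selected cells.

    ``fold`` multiplies the base mean in cells matching ``carriers``.
    If ``on_frac_carrier``/``on_frac_other`` are set, the gene is gated
    per cell by a Bernoulli switch (zero-inflation), which lets planted
    differential genes control their expressed fractions directly.
    """

    genes: tuple[str, ...]
    carriers: Mapping[str, object]
    fold: float = 8.0
    on_frac_carrier: Optional[float] = None
    on_frac_other: Optional[float] = None


@dataclass(frozen=True)
class CnvSegment:
    chrom: str
    start: int
    end: int
    copy_ratio: float
    carriers: Mapping[str, object]

    def __post_init__(self) -> None:
        if self.copy_ratio <= 0:
            raise ValueError("copy_ratio must be > 0")
        if not 0 <= self.start < self.end:
            raise ValueError("bad segment bounds")


@dataclass(frozen=True)
class MitoClone:
    """A mitochondrial clone: shared variant sites at a common heteroplasmy.

    ``penetrance`` < 1 makes only that fraction of selector-matched cells
    actual clone members (tumor tissue usually contains admixed normal
    epithelium).
    """

    clone_id: str
    sites: tuple[str, ...]  # "position_altbase" strings, e.g. "6719_G"
    carriers: Mapping[str, object]
    allele_fraction: float = 0.9
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.allele_fraction <= 1:
            raise ValueError("allele fraction must lie in [0, 1]")
        if not 0 < self.penetrance <= 1:
            raise ValueError("penetrance must lie in (0, 1]")


def _default_groups() -> tuple[GroupSpec, ...]:
    arms = [GroupSpec(t, "invivo") for t in ("tumor", "normal")]
    for tissue, medium, term in itertools.product(
        ("tumor", "normal"), ("chem", "cond"), ("short", "long")
    ):
        arms.append(GroupSpec(tissue, "organoid", medium, term))
    return tuple(arms)


def _default_type_proportions() -> dict:
    # in vivo tissue carries stroma and immune cells; organoid culture is
    # epithelium-dominated, with a larger mesenchymal-like fraction in
    # chemical-defined medium than in conditioned medium
    return {
        "invivo": {"epithelial": 0.75, "mesenchymal": 0.15, "immune": 0.10},
        "chem": {"epithelial": 0.865, "mesenchymal": 0.135, "immune": 0.0},
        "cond": {"epithelial": 0.95, "mesenchymal": 0.05, "immune": 0.0},
    }


@dataclass
class TruthConfig:
    """Full specification of the synthetic cohort.

    Defaults describe a two-patient scaled cohort with one clonal CNV
    gain and one three-site mitochondrial tumor clone per the study
    design; see docs/methods.md for the rationale behind each default.
    """

    n_patients: int = 2
    groups: tuple[GroupSpec, ...] = field(default_factory=_default_groups)
    cells_per_group: int = 25
    n_genes: int = 6000
    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 120_000_000),
        ("chr2", 110_000_000),
        ("chr3", 100_000_000),
        ("chr4", 90_000_000),
        ("chr5", 80_000_000),
        ("chrM", 16_569),
    )
    cell_type_programs: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in MAJOR_MARKERS.items()}
    )
    type_proportions: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_type_proportions
    )
    program_strength: float = 8.0
    # lineage markers are near-silent off-lineage and robustly expressed
    # on-lineage; their means are set directly rather than folded
    marker_base_mean: float = 0.05
    marker_carrier_mean: float = 20.0
    extra_programs: tuple[Program, ...] = ()
    cnv_segments: tuple[CnvSegment, ...] = (
        CnvSegment("chr1", 30_000_000, 60_000_000, 2.0, {"tissue": "tumor"}),
    )
    mito_clones: tuple[MitoClone, ...] = (
        MitoClone("clone1", ("6719_G", "12948_T", "7397_G"), {"tissue": "tumor"}, 0.9),
    )
    mito_noise_sites: int = 50
    library_size_lognormal: tuple[float, float] = (0.0, 0.3)
    dropout_rate: float = 0.02
    dispersion: float = 0.5  # NB dispersion; variance = m + dispersion * m^2
    depth_model: float = 30.0  # mean mitochondrial site depth
    error_rate: float = 0.005  # alt-read rate at non-clone sites
    mito_read_fraction: float = 0.134  # median per-cell mitochondrial share
    base_mean_lognormal: tuple[float, float] = (np.log(0.7), 1.0)
    wgs_base_rate: float = 10_000.0  # expected reads per diploid 10-Mb window
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1 or self.cells_per_group < 1 or self.n_genes < 1:
            raise ValueError("population sizes must be positive")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.depth_model <= 0:
            raise ValueError("depth_model must be > 0")
        lengths = dict(self.genome)
        for seg in self.cnv_segments:
            if seg.chrom not in lengths or seg.end > lengths[seg.chrom]:
                raise ValueError(f"CNV segment outside chromosome bounds: {seg}")

    def small(self, **overrides) -> "TruthConfig":
        """A desk-scale variant for read-level and end-to-end runs."""
        base = replace(
            self,
            n_patients=1,
            cells_per_group=8,
            n_genes=300,
            base_mean_lognormal=(np.log(0.5), 1.0),
        )
        return replace(base, **overrides)


@dataclass
class GroundTruth:
    """Everything the generator knows: the answer key for the pipeline."""

    config: TruthConfig
    records: list[CellRecord]
    cells: pd.DataFrame  # indexed by cell id: provenance + cell_type + clone_id
    barcodes: dict[str, str]  # cell id -> 8-mer barcode
    genes: pd.DataFrame  # gene track: chrom, start, ordinal
    base_mean: pd.Series
    gene_copy_ratio: pd.DataFrame  # genes x cells expected copy ratio
    mito_fraction: pd.Series  # per-cell planted mitochondrial read share
    wgs_samples: pd.DataFrame  # sample id -> patient, tissue, depth factor
    window_truth: pd.DataFrame  # windows x samples true copy ratio

    def carriers(self, selector: Mapping[str, object]) -> list[str]:
        return [r.cell_id for r in self.records if r.matches(selector)]


# ---------------------------------------------------------------------------
# population / expression


def _build_cells(config: TruthConfig, rng: np.random.Generator):
    records, types = [], []
    type_names = list(config.cell_type_programs) or ["epithelial"]
    for p in range(1, config.n_patients + 1):
        for grp in config.groups:
            key = grp.medium if grp.source == "organoid" else "invivo"
            props = config.type_proportions.get(key)
            if props:
                names = [t for t in type_names if t in props]
                weights = np.array([props[t] for t in names], dtype=float)
                weights = weights / weights.sum()
            else:
                names, weights = type_names, np.full(len(type_names), 1 / len(type_names))
            for i in range(config.cells_per_group):
                cid = f"P{p}_{grp.tissue}_{grp.source}_{grp.medium}_{grp.term}_c{i:03d}"
                records.append(
                    CellRecord(cid, f"P{p}", grp.tissue, grp.source, grp.medium, grp.term)
                )
                types.append(str(rng.choice(names, p=weights)))
    return records, types


def _build_genes(config: TruthConfig, rng: np.random.Generator) -> pd.DataFrame:
    autosomes = [(c, l) for c, l in config.genome if c != "chrM"]
    has_mt = any(c == "chrM" for c, _ in config.genome)
    n_named = len(NAMED_GENES)
    n_mito = min(13, max(3, config.n_genes // 100)) if has_mt else 0
    n_filler = max(0, config.n_genes - n_named - n_mito)
    ids = NAMED_GENES + [f"G{i:05d}" for i in range(n_filler)]
    lens = np.array([l for _, l in autosomes], dtype=float)
    chrom_of = rng.choice([c for c, _ in autosomes], size=len(ids), p=lens / lens.sum())
    starts = [int(rng.integers(0, dict(autosomes)[c])) for c in chrom_of]
    all_ids, all_chroms, all_starts = list(ids), list(chrom_of), starts
    if has_mt:
        mt_len = dict(config.genome)["chrM"]
        for j in range(n_mito):
            all_ids.append(f"MT-G{j:02d}")
            all_chroms.append("chrM")
            all_starts.append(int((j + 0.5) * mt_len / n_mito))
    return make_gene_track(all_ids, all_chroms, all_starts)


def _segment_gene_mask(genes: pd.DataFrame, seg: CnvSegment) -> np.ndarray:
    return (
        (genes["chrom"] == seg.chrom)
        & (genes["start"] >= seg.start)
        & (genes["start"] < seg.end)
    ).to_numpy()


def _check_segment_overlap(config: TruthConfig, records: list[CellRecord]) -> None:
    segs = config.cnv_segments
    for a, b in itertools.combinations(segs, 2):
        if a.chrom != b.chrom or a.end <= b.start or b.end <= a.start:
            continue
        cells_a = {r.cell_id for r in records if r.matches(a.carriers)}
        if any(r.cell_id in cells_a for r in records if r.matches(b.carriers)):
            raise ValueError(
                f"overlapping CNV segments on shared carrier cells: {a} / {b}"
            )


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson; dispersion 0 degenerates to Poisson."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, 1.0, size=mean.shape) * dispersion * mean
    return rng.poisson(lam)


def generate_population(config: TruthConfig) -> tuple[GroundTruth, ExpressionMatrix]:
    """Draw the full synthetic cohort and its UMI count matrix.

    Per gene g and cell c the expected count is
    ``base_mean[g] * program factor * copy_ratio[g, c] * library[c]``,
    rescaled so the cell's mitochondrial share matches its planted value;
    counts are negative-binomial draws then zeroed with probability
    ``dropout_rate``. TPM is computed from the realized counts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records, cell_types = _build_cells(config, rng)
    _check_segment_overlap(config, records)
    genes = _build_genes(config, rng)
    gene_ids = genes.index.to_numpy()
    n_g, n_c = len(gene_ids), len(records)
    cell_ids = [r.cell_id for r in records]

    base_mean = pd.Series(
        rng.lognormal(*config.base_mean_lognormal, size=n_g), index=genes.index
    )
    rate = np.tile(base_mean.to_numpy()[:, None], (1, n_c))

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    # cell-type marker programs: marker genes get a low off-lineage base
    # mean and a fixed strong on-lineage mean
    for tname, markers in config.cell_type_programs.items():
        rows = [gene_pos[g] for g in markers if g in gene_pos]
        if not rows:
            continue
        for r in rows:
            rate[r, :] = config.marker_base_mean
            base_mean.iloc[r] = config.marker_base_mean
        cols = [j for j, t in enumerate(cell_types) if t == tname]
        if cols:
            rate[np.ix_(rows, cols)] = config.marker_carrier_mean
    # extra condition programs (e.g. planted tumor-specific genes)
    for prog in config.extra_programs:
        rows = [gene_pos[g] for g in prog.genes if g in gene_pos]
        if not rows:
            continue
        carrier = np.array([r.matches(prog.carriers) for r in records])
        sub = rate[np.ix_(rows, np.where(carrier)[0])]
        rate[np.ix_(rows, np.where(carrier)[0])] = sub * prog.fold
        if prog.on_frac_carrier is not None:
            gate = rng.random((len(rows), n_c))
            on = np.where(
                carrier[None, :],
                gate < prog.on_frac_carrier,
                gate < (prog.on_frac_other or 0.0),
            )
            rate[rows, :] *= on

    # planted CNV segments multiply expression of covered genes in carriers
    copy_ratio = np.ones((n_g, n_c))
    for seg in config.cnv_segments:
        mask = _segment_gene_mask(genes, seg)
        carrier = np.array([r.matches(seg.carriers) for r in records])
        copy_ratio[np.ix_(mask, carrier)] = seg.copy_ratio
    rate *= copy_ratio

    # per-cell mitochondrial share: rescale chrM genes to the planted share
    is_mt = (genes["chrom"] == "chrM").to_numpy()
    mito_frac = np.clip(
        rng.normal(config.mito_read_fraction, 0.02, size=n_c), 0.0, 0.9
    )
    if is_mt.any() and (~is_mt).any() and config.mito_read_fraction > 0:
        mt_tot = rate[is_mt].sum(axis=0)
        rest_tot = rate[~is_mt].sum(axis=0)
        scale = np.where(
            mt_tot > 0, mito_frac / (1 - mito_frac) * rest_tot / np.maximum(mt_tot, 1e-12), 1.0
        )
        rate[is_mt] *= scale
    else:
        mito_frac = np.zeros(n_c)

    lib = rng.lognormal(*config.library_size_lognormal, size=n_c)
    rate *= lib[None, :]

    counts = _nb_counts(rng, rate, config.dispersion)
    if config.dropout_rate > 0:
        counts = np.where(rng.random(counts.shape) < config.dropout_rate, 0, counts)

    counts_df = pd.DataFrame(
        counts.astype(np.int64), index=genes.index, columns=pd.Index(cell_ids, name="cell")
    )
    cells = records_to_frame(records)
    cells["cell_type"] = cell_types
    clone_ids = []
    for r in records:
        cid = "wild_type"
        for clone in config.mito_clones:
            if r.matches(clone.carriers) and (
                clone.penetrance >= 1 or rng.random() < clone.penetrance
            ):
                cid = clone.clone_id
                break
        clone_ids.append(cid)
    cells["clone_id"] = clone_ids

    barcodes = _assign_barcodes(cell_ids, rng)
    wgs_samples, window_truth = _wgs_truth(config, rng)
    truth = GroundTruth(
        config=config,
        records=records,
        cells=cells,
        barcodes=barcodes,
        genes=genes,
        base_mean=base_mean,
        gene_copy_ratio=pd.DataFrame(copy_ratio, index=genes.index, columns=cell_ids),
        mito_fraction=pd.Series(mito_frac, index=cells.index),
        wgs_samples=wgs_samples,
        window_truth=window_truth,
    )
    matrix = ExpressionMatrix(
        counts=counts_df, genes=genes, cells=cells, tpm=tpm_normalize(counts_df)
    )
    return truth, matrix


_BASES = np.array(list("ACGT"))


def _assign_barcodes(cell_ids: list[str], rng: np.random.Generator) -> dict[str, str]:
    seen: set[str] = set()
    out = {}
    for cid in cell_ids:
        while True:
            bc = "".join(rng.choice(_BASES, size=8))
            if bc not in seen:
                seen.add(bc)
                out[cid] = bc
                break
    return out


# ---------------------------------------------------------------------------
# reads


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _distinct_umis(rng: np.random.Generator, n: int, used: set[str]) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        u = _random_seq(rng, 8)
        if u not in used:
            used.add(u)
            out.append(u)
    return out


FAIL_KINDS = ("short", "lowqual", "nrich", "unknown_barcode")


def synthesize_reads(
    truth: GroundTruth,
    counts: pd.DataFrame,
    fail_fraction: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> list[ReadPair]:
    """Emit one STRT read pair per counted molecule, plus injected failures.

    R2 carries the cell's 8-nt barcode then an 8-nt UMI (distinct per
    gene and cell); R1 is a random cDNA fragment with a 3' poly-A tail,
    Q40 qualities, and the gene of origin tagged in the read name
    (``gene=``), the alignment surrogate. With ``fail_fraction`` f > 0 a
    Poisson(total * f / (1-f)) number of deliberately failing reads is
    appended, labeled ``fail=<kind>`` in the name, so the realized
    failing fraction concentrates on f.
    """
    rng = rng or np.random.default_rng(truth.config.seed + 1)
    missing = [c for c in counts.columns if c not in truth.barcodes]
    if missing:
        raise ValueError(f"cells lack whitelist barcodes: {missing[:3]}")
    pairs: list[ReadPair] = []
    idx = 0
    arr = counts.to_numpy()
    gene_ids = counts.index.to_numpy()
    for j, cell in enumerate(counts.columns):
        bc = truth.barcodes[cell]
        used: set[str] = set()
        nz = np.nonzero(arr[:, j])[0]
        for gi in nz:
            for umi in _distinct_umis(rng, int(arr[gi, j]), used):
                body = _random_seq(rng, int(rng.integers(60, 120)))
                r1 = body + "A" * 15
                pairs.append(
                    ReadPair(
                        read_name=f"r{idx:07d};cell={cell};gene={gene_ids[gi]}",
                        r1_seq=r1,
                        r1_qual="I" * len(r1),
                        r2_seq=bc + umi + _random_seq(rng, 4),
                    )
                )
                idx += 1
    if fail_fraction > 0:
        if not 0 < fail_fraction < 1:
            raise ValueError("fail_fraction must lie in (0, 1)")
        n_fail = int(rng.poisson(len(pairs) * fail_fraction / (1 - fail_fraction)))
        whitelisted = set(truth.barcodes.values())
        cells = list(counts.columns)
        for k in range(n_fail):
            kind = FAIL_KINDS[int(rng.integers(0, len(FAIL_KINDS)))]
            cell = cells[int(rng.integers(0, len(cells)))]
            bc = truth.barcodes[cell]
            umi = _random_seq(rng, 8)
            if kind == "unknown_barcode":
                while True:
                    bc = _random_seq(rng, 8)
                    if bc not in whitelisted:
                        break
                r1 = _random_seq(rng, 80)
                qual = "I" * len(r1)
            elif kind == "short":
                r1 = _random_seq(rng, 20) + "A" * 15
                qual = "I" * len(r1)
            elif kind == "lowqual":
                r1 = _random_seq(rng, 80)
                qual = "#" * 50 + "I" * 30  # well over half the bases at Q2
            else:  # nrich
                body = list(_random_seq(rng, 80))
                for pos in rng.choice(80, size=12, replace=False):
                    body[pos] = "N"
                r1 = "".join(body)
                qual = "I" * len(r1)
            pairs.append(
                ReadPair(
                    read_name=f"f{k:07d};fail={kind}",
                    r1_seq=r1,
                    r1_qual=qual,
                    r2_seq=bc + umi + _random_seq(rng, 4),
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# mitochondrial pileup


def simulate_mito_pileup(
    truth: GroundTruth,
    depth_model: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Per-cell depth/alt counts at clone sites plus error-only noise sites.

    Depth is Poisson(depth_model); alt reads are Binomial(depth, af) with
    af = the clone's allele fraction at its sites for carrier cells and
    the sequencing-error rate everywhere else.
    """
    config = truth.config
    depth_mean = config.depth_model if depth_model is None else depth_model
    if depth_mean <= 0:
        raise ValueError("depth_model must be > 0")
    rng = rng or np.random.default_rng(config.seed + 2)
    clone_sites = [s for clone in config.mito_clones for s in clone.sites]
    noise_sites = []
    used_pos = {int(s.split("_")[0]) for s in clone_sites}
    mt_len = dict(config.genome).get("chrM", 16_569)
    while len(noise_sites) < config.mito_noise_sites:
        pos = int(rng.integers(100, mt_len))
        if pos not in used_pos:
            used_pos.add(pos)
            noise_sites.append(f"{pos}_{_BASES[rng.integers(0, 4)]}")
    sites = clone_sites + noise_sites

    site_af = {}
    for clone in config.mito_clones:
        # realized membership from the truth table (honours penetrance)
        carrier_ids = set(truth.cells.index[truth.cells["clone_id"] == clone.clone_id])
        for s in clone.sites:
            site_af[s] = (carrier_ids, clone.allele_fraction)

    rows = []
    for cell in truth.cells.index:
        for s in sites:
            depth = int(rng.poisson(depth_mean))
            carriers, af = site_af.get(s, (frozenset(), None))
            p = af if cell in carriers else config.error_rate
            alt = int(rng.binomial(depth, p)) if depth > 0 else 0
            rows.append((cell, s, depth, alt))
    return pd.DataFrame(rows, columns=["cell", "site", "depth", "alt"])


# ---------------------------------------------------------------------------
# WGS windows


def _wgs_truth(config: TruthConfig, rng: np.random.Generator):
    """Bulk WGS samples (tumor + normal per patient) and true window ratios."""
    samples = []
    for p in range(1, config.n_patients + 1):
        for tissue in ("tumor", "normal"):
            samples.append(
                {
                    "sample": f"P{p}_{tissue}",
                    "patient": f"P{p}",
                    "tissue": tissue,
                    "depth_factor": float(rng.lognormal(0.0, 0.2)),
                }
            )
    sample_df = pd.DataFrame(samples).set_index("sample")

    windows = []
    for chrom, length in config.genome:
        if chrom == "chrM":
            continue
        for w in range(int(np.ceil(length / WINDOW_BP))):
            windows.append((chrom, w))
    truth = pd.DataFrame(
        1.0,
        index=pd.MultiIndex.from_tuples(windows, names=["chrom", "widx"]),
        columns=sample_df.index,
    )
    for seg in config.cnv_segments:
        sample_sel = {
            k: v for k, v in seg.carriers.items() if k in ("tissue", "patient")
        }
        for sample, row in sample_df.iterrows():
            if all(
                row.get(k) == v or (isinstance(v, (list, tuple, set)) and row.get(k) in v)
                for k, v in sample_sel.items()
            ):
                for (chrom, widx) in truth.index:
                    if chrom != seg.chrom:
                        continue
                    lo, hi = widx * WINDOW_BP, (widx + 1) * WINDOW_BP
                    ov = max(0, min(hi, seg.end) - max(lo, seg.start))
                    if ov > 0:
                        frac = ov / WINDOW_BP
                        truth.loc[(chrom, widx), sample] = 1 + frac * (seg.copy_ratio - 1)
    return sample_df, truth


def simulate_wgs_windows(
    truth: GroundTruth,
    base_rate: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Windowed read counts per bulk sample: Poisson(base_rate x ratio x depth)."""
    config = truth.config
    rate0 = config.wgs_base_rate if base_rate is None else base_rate
    rng = rng or np.random.default_rng(config.seed + 3)
    lam = truth.window_truth * rate0
    lam = lam * truth.wgs_samples["depth_factor"]
    counts = rng.poisson(lam.to_numpy())
    return pd.DataFrame(counts, index=truth.window_truth.index, columns=lam.columns)
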