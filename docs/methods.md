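# Methods

This note records the models, parameter choices and numerical conventions
behind `orgscope`, and what the synthetic-data tests do and do not show.

## The synthetic cohort model

The generator (`orgscope.synthdata`) emulates the design of a paired
tumor/normal organoid study: `n_patients` patients, each contributing cells
from in-vivo tissue and from organoids cultured in a chemical-defined or a
conditioned medium at short and long term (10 arms by default,
`cells_per_group` cells each). It produces every input the pipeline
consumes, with truth labels, from one seeded `numpy.random.Generator`; a
fixed `TruthConfig` reproduces byte-identical outputs.

**Expression.** For gene *g* and cell *c* the expected UMI count is

    mu[g,c] = base_mean[g] × program(g, type(c)) × copy_ratio[g,c] × lib[c]

with counts drawn negative-binomially (gamma–Poisson, dispersion 0.5, so
Var = μ + 0.5 μ²) and then zeroed with probability `dropout_rate`. Choices
and rationale:

- `base_mean` ~ lognormal(log 0.7, 1.0) over a 6,000-gene universe: gives
  per-cell totals of a few thousand molecules and 2,000–3,000 detected
  genes, the regime in which a ">2000 detected genes" cell filter is
  meaningful for deep plate-based STRT libraries.
- Dispersion 0.5 is a standard overdispersion level for UMI counts; it is
  configurable and 0 degenerates to Poisson.
- `dropout_rate` = 0.02. Deep plate-based data has little technical
  dropout beyond sampling (which the NB already produces); the parameter
  models residual capture failure and its degenerate value 1 yields an
  all-zero matrix while truth labels are still emitted.
- Lineage markers (EPCAM; VIM/THY1; PTPRC; and the epithelial subtype
  panel) are handled specially: off-lineage mean 0.05, on-lineage mean 20
  (≈3,000 TPM, the observed scale for genes like EPCAM in epithelium).
  Real lineage markers are orders of magnitude specific; folding a
  lognormal base mean by 8 would let an unelevated high-baseline marker
  outscore an elevated low-baseline one, which no real marker panel does.
- Planted condition programs (`Program`) multiply means by `fold`
  (default 8) in selector-matched cells and can gate expression per cell
  (`on_frac_carrier` / `on_frac_other`) to control expressed fractions
  directly — this is how differential genes with pct 0.8 vs 0.05 are
  planted.
- Library factors are lognormal(0, 0.3); CNV segments multiply the means
  of covered genes in carrier cells by their copy ratio. Overlapping
  segments on shared carriers are rejected as a config error.
- The mitochondrial share of each cell's library is planted directly
  (Normal(0.134, 0.02), clipped): chrM gene rates are rescaled so the
  expected mitochondrial fraction equals the planted value regardless of
  CNVs or programs. Because the NB is heavily overdispersed at
  mitochondrial-gene means, the realized median sits ~0.5 percentage
  points below the planted value; recovery tests use a ±1 point band.

**Reads.** One read pair per counted molecule: R2 = 8-nt cell barcode +
8-nt UMI (UMIs distinct within a gene×cell); R1 = random cDNA of 60–120 nt
plus a 15-nt poly-A tail at Q40, with the gene of origin tagged in the read
name. The tag is the alignment surrogate: read mapping is outside this
package's scope, so quantification is tested without an aligner (an
external read→gene TSV is accepted for real data). Deliberately failing
reads — short, low-quality, N-rich, unknown-barcode — are injected at a
configurable fraction (Poisson-distributed count, so the realized fraction
concentrates on the target) and labeled in the read name.

**Mitochondrial pileup.** Per cell and site, depth ~ Poisson(`depth_model`,
default 30) and alt ~ Binomial(depth, af), where af is the clone's
heteroplasmy (default 0.9) for clone members and the sequencing-error rate
0.005 otherwise. Clone membership is the carrier selector thinned by
`penetrance`, modelling normal-epithelium admixture in tumor tissue.

**WGS windows.** Bulk tumor/normal samples per patient; window counts ~
Poisson(base_rate × true copy ratio × sample depth factor) with the true
ratio overlap-weighted where a segment partially covers a window.

**What the generator does not emulate:** batch effects, gene length or GC
bias, barcode sequencing errors, UMI collisions or PCR-error UMIs,
doublets, ambient RNA, expression-coupled dropout curves, mappability or
GC structure in WGS depth. Passing tests therefore demonstrate
correctness of the pipeline's arithmetic and its behaviour under the
modelled noise sources, not robustness to every artefact of real data.

## Read and cell QC conventions

Boundary readings are deliberate and tested:

- Poly-A trimming removes the longest 3′ suffix of length ≥ 6 with
  A-fraction ≥ 0.9 (tolerates an isolated miscall inside the tail;
  idempotent by construction). QC criteria are evaluated *after*
  trimming.
- Length "at least 40 bp": 40 passes. Quality "more than half of bases
  above Q38": exactly half fails. N content "less than 10%": exactly 10%
  fails. Phred33 throughout.
- Barcodes match the whitelist exactly; no error correction or rescue.
- "Detected gene" means TPM > 0; the >2000-gene and >0.6 top-2-correlation
  cell filters are strict, with the second-highest Pearson correlation
  computed on log2(TPM+1) over all genes against the full pre-filter
  population.

## Expression CNV

Relative expression is E = log2(TPM/10 + 1), the convention of the
moving-average CNV method this module follows; genes with mean E > 1.5
across QC-passed cells enter. Each gene's score averages E over the window
of its 100 ordinal neighbours on the same chromosome — 50 per side
*including the gene itself*, shrunk at chromosome ends, never crossing a
chromosome. Scores are centered per gene across **all** cells (no
reference group), then averaged within half-open 10-Mb windows anchored at
coordinate 0. Empty windows are missing, not zero. No clamping,
re-standardization or segmentation is applied. A chromosome carrying a
single filtered gene degenerates to that gene's centered E, with a
warning.

## Mitochondrial lineage

A site call needs ≥ 9 reads (total depth; below that it is low-coverage);
callable sites are mutant at variant allele fraction ≥ 0.2 — the VAF
cutoff is this package's parameter, exposed as `min_vaf`, since binary
mutant/wild-type heatmaps do not pin one down. Tumor-specific sites
require ≥ 20% mutant among callable tumor cells and ≤ 5% among callable
normal cells (both configurable). Clone assignment is per cell over its
callable specific sites: mutant at ≥ half → tumor clone keyed by the
exact mutant-site subset; mutant at none → wild-type; mutant at fewer
than half → wild-type (majority rule); no callable site → unassignable.
Cells observing only part of the panel are matched to the nearest
fully-observed clone pattern by Hamming distance on their callable sites,
ties going to unassignable. Assignment is invariant to row and site
order.

## Networks, differential genes, signatures

Tumor-specific genes: pct(expressed, TPM > 0) ≥ 0.25 in the foreground
group, |pct difference| ≥ 0.25, and log2((mean_A+1)/(mean_B+1)) ≥ 1.5 —
pseudocount +1 on mean TPM, one documented convention among the several in
circulation. The network is gene–gene Pearson correlation (log2(TPM+1))
across in-vivo tumor cells; the adjacency cutoff r ≥ 0.3 is this
package's default (none is canonical), and degree-<3 pruning iterates to a
fixed point (each removal can demote a neighbour); a single-pass variant
is available. Node colors are group-mean log2 fold changes. Co-expression
(e.g. EPCAM/VIM) uses TPM > 1 for positivity; expression bins default to
{0}, (0,10], (10,100], (100,∞) TPM with a chi-square test (no continuity
correction; Fisher fallback for sparse 2×2) — both the edges and the test
are stand-ins where no standard is fixed, and both are configurable.

## WGS window ratios

Reads are assigned to the half-open 10-Mb window containing their start
position. Stage 1 divides by the sample total; stage 2 by the cross-sample
per-window mean, which makes each window's ratios average 1 and *biases
the reference when tumor samples are included* — e.g. one 0.5-copy sample
among three diploids yields ≈0.57 rather than 0.5 in the deleted windows.
This is implemented as stated; a normals-only reference is available via
`wgs_cnv(reference_samples=...)`. Both the ratio and 2×ratio (diploid
copy-number scale) are emitted.

## Orchestration and problem sizes

The pipeline derives per-stage seeds from the single run seed by fixed
offsets, so any stage re-run in isolation reproduces its slice of a full
run, and two runs with one config are byte-identical. Simulation-backed
tests use cohorts of 80–800 cells and 100–6,000 genes with 10–50
replicates per stochastic claim — sizes at which every planted effect
(copy ratios down to 1.25, two-clone mixtures at depth 30, 8-fold
differential programs) is comfortably detectable in seconds per
replicate; the acceptance script states the exact `n` it used next to
each reported value.

## Known limitations

- Marker-score typing needs every major type's markers in the matrix and
  is sensitive to marker dropout in very shallow libraries; the paperless
  alternative (cluster-then-annotate) is deliberately out of scope.
- Clone identity is a site-subset key, not a phylogeny; nested or
  overlapping clones with shared sites will merge or split by the
  majority rule.
- The expression-CNV score is relative to the cohort average; a CNV
  present in nearly all cells is absorbed by centering.
- UMI deduplication is exact-sequence; directional-network collapsing of
  sequencing-error UMIs is not implemented.
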