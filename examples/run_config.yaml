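# Desk-scale end-to-end run: one patient, 8 cells per arm, 300 genes.
# The detected-gene QC threshold is scaled to the 300-gene universe
# (the production default, >2000 genes, assumes a genome-scale matrix).
seed: 7
outdir: orgscope_demo
small_cohort: true
fail_fraction: 0.10
qc:
  min_genes: 60
  min_top2_corr: 0.3
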