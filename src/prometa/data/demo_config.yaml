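# Bundled small synthetic study: three planted loci (one with a secondary
# signal), five companion traits, two cis-eQTL genes, and a planted
# annotation enrichment. Runs end-to-end in well under five minutes.
seed: 7
out_dir: runs/demo
bmi_adjusted: true
n_cohorts: 16
cohort_size: 800
companion_n: 20000
blocks:
  - {n_variants: 70, maf_low: 0.1, maf_high: 0.5, decay: 0.9, chrom: "1"}
  - {n_variants: 70, maf_low: 0.1, maf_high: 0.5, decay: 0.9, chrom: "1"}
  - {n_variants: 70, maf_low: 0.1, maf_high: 0.5, decay: 0.9, chrom: "2"}
  - {n_variants: 70, maf_low: 0.1, maf_high: 0.5, decay: 0.9, chrom: "2"}
  - {n_variants: 60, maf_low: 0.05, maf_high: 0.5, decay: 0.85, chrom: "2"}
  # null background blocks keep the genomic-control median well calibrated
  - {n_variants: 160, maf_low: 0.05, maf_high: 0.5, decay: 0.5, chrom: "3"}
  - {n_variants: 160, maf_low: 0.05, maf_high: 0.5, decay: 0.5, chrom: "4"}
causal:
  # locus A: shared with fasting glucose and T2D (colocalizes)
  - {block: 0, index: 20, traits: {proinsulin: 0.16, FG: 0.12, T2D: 0.12}}
  # locus B: primary + secondary proinsulin signal (conditional analysis)
  - {block: 1, index: 15, traits: {proinsulin: 0.18}}
  - {block: 1, index: 45, traits: {proinsulin: 0.14}}
  # locus C: opposite direction on fasting glucose
  - {block: 2, index: 30, traits: {proinsulin: 0.14, FG: -0.12}}
eqtl_genes:
  - {gene: GENE_A, block: 0, index: 20, beta: 0.8, n_samples: 420, mode: shared}
  - {gene: GENE_C, block: 2, index: 50, beta: 0.8, n_samples: 420, mode: distinct}
enrichment:
  fold: 4.0
  width: 400
  background_fraction: 0.05
  n_genes: 40
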