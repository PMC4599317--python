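# Default pipeline parameters. Every analysis threshold appears here once.
window: 500000                # cis window in bp, boundary inclusive
detection_min_fraction: 0.75  # probes need >= this fraction of samples passing
detection_p_threshold: 0.01   # per-sample detection p-value cutoff
reference_range_min: 0.20     # 95% reference range for variable-probe selection
outlier_n_pcs: 8              # PCs inspected for sample outliers
outlier_z_threshold: 3.0      # per-PC |z| rule for sample exclusion
min_homozygote_count: 10      # below this, homozygotes merge with heterozygotes
q_threshold: 0.05             # scan and enrichment significance cutoff
promoter_window: 1500         # bp around the TSS counted as promoter
power_alpha: 0.05             # level for replication power

simulate:
  enabled: true
  n_samples: 350
  n_snps: 12
  probes_per_snp: 40
  n_reference_probes: 43
  noise_sd: 0.25
  seed: 0
  effects: {}                 # "snp_id|probe_id": delta (M units per risk allele)

paths:
  covariates: null
  genotypes: null
  beta: null
  detection_p: null
  snp_manifest: null
  probe_manifest: null
  genes: null
  states: {}                  # tissue -> BED4 path
  interactions: null
  enhancers: null
  reference_probes: null      # text file, one probe id per line

output_dir: meqtl_out
seed: 0
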