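# meqtlscan

Cis methylation-QTL (meQTL) discovery for array-based DNA methylation
cohorts: association of SNP risk-allele dosages with methylation at
proximal CpG sites, adjusted for covariates and blood cell-type
composition, with Storey-q false-discovery control and genomic-context
enrichment of the associated CpGs. It is aimed at epigenomics analysts who
want a tested, reproducible reimplementation of this analysis style, plus a
synthetic-cohort generator with known ground truth so every stage can be
validated without access to human subject data.

## The model

For each CpG site *k*, methylation is analysed on the M scale
(M = log2(β / (1 − β))) with the linear model

```
M_k = a_k + b_kS·S + b_kA·A + b_kW·W + b_kG·G + b_kPC1·PC1 + b_kPC2·PC2 + ε_k
```

where S is sex (female = 1), A age in years, W weight category (lean = 0,
overweight = 1, obese = 2), G the risk-allele dosage (0/1/2; a homozygote
class with fewer than 10 carriers is collapsed into the heterozygotes), and
PC1/PC2 are the first two principal components of a panel of cell-type
discriminating CpGs, serving as a surrogate for blood cell composition.
The SNP p-value is a likelihood-ratio test of the full against the no-G
fit, LRT = n·ln(RSS₀/RSS₁) ~ χ²(1); the effect size is the partial
R² = 1 − RSS₁/RSS₀, the share of covariate-adjusted methylation variance
explained by the genotype. SNP–CpG pairs are formed within ±500 kb
(boundary inclusive) and q-values are computed over all tested pairs with
the smoother estimate of π₀; pairs with q < 0.05 are called associated.

Associated CpGs are then classified against gene models (promoter =
±1500 bp of a TSS, gene body, intergenic, ambiguous), per-tissue chromatin
state categories, enhancer intervals, and ChIA-PET-style interaction
anchors; enrichment against the tested background uses Fisher's exact test
(q over each family), and interaction-count distributions are compared with
a Mann–Whitney U test. A noncentral-F power module (Cohen f² = R²/(1 − R²),
λ = f²·(u+v+1)) gives replication power for each hit.

## Worked example

A full synthetic run — 350 samples, 4 SNPs with 30 candidate CpGs each,
two planted effects (+0.8 and −0.6 M units per risk allele):

```yaml
# cfg.yaml
simulate:
  n_samples: 350
  n_snps: 4
  probes_per_snp: 30
  n_reference_probes: 43
  effects:
    "rs0001|cg0000000": 0.8
    "rs0003|cg0020003": -0.6
```

```
$ meqtl run --config cfg.yaml --out out --seed 9
```

The run manifest (stderr) reports `n_samples_retained: 342` (eight samples
failed the per-PC |z| > 3 outlier rule), `n_pairs_tested: 120` and
`n_significant: 2`. The rendered `out/report.md` begins:

```
Tested pairs: 120; significant (q < 0.05): 2 at 2 SNPs.

## rs0001
Associated CpGs: 1 of 30 tested (median distance 459798 bp)
- cg0000000: distance 459798 bp, coef +0.807 M/allele, q 4.11e-135; class intergenic; ...

## rs0002
Associated CpGs: none

## rs0003
Associated CpGs: 1 of 30 tested (median distance 350672 bp)
- cg0020003: distance 350672 bp, coef -0.608 M/allele, q 1.66e-99; class gene_body; ...
```

Both planted effects — and nothing else — are recovered, with coefficient
estimates (+0.807, −0.608) close to the planted values. Replication power
for a hit explaining 8 % of adjusted variance in a 62-sample cohort:

```
$ meqtl power --r2 0.08 --n 62 --terms 6
0.5900
```

The same functionality is available as a library: `simulate_dataset`,
`filter_probes`/`beta_to_m`/`cell_surrogate`, `CisMeQTLScanner`,
`classify_regions`/`fisher_enrichment`, `power_from_r2`, and
`run_pipeline`. The scanner and preprocessing steps follow scikit-learn
conventions (`fit`/`transform`, fitted attributes with a trailing
underscore).

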