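# Annotated pipeline configuration for `eqtloverlap run --config <file>`.
# Every field is optional; values shown are the defaults used when omitted.

out_dir: eqtloverlap_run     # where reports and the run log are written
seed: 0                      # single seed driving all randomness in the run

# analysis parameters
cis_window_bp: 1000000       # cis region: +/- 1 Mb around the TSS, inclusive
fdr: 0.05                    # study-wide Benjamini-Hochberg FDR level
r2_threshold: 0.8            # proxy-SNP LD threshold (0.5 for sensitivity runs)
proxy_window_bp: 100000      # proxy search window: +/- 100 kb around the eSNP
overlap_mode: best_per_gene  # or all_significant (intersect all significant SNPs)
proxy_criterion: intersect   # or contains (eSNP_j must lie in proxies of eSNP_i)
adjust_reps: 20              # subsampling replicates for the power estimate

# synthetic study pair (omit this block to disable simulation; the library
# API accepts external matrices/summary lists instead)
simulate:
  n_genes: 500               # genes per study; half carry an eQTL by default
  n_individuals_i: 1000      # discovery study sample size
  n_individuals_j: 200       # replication study sample size
  pi_true: 0.3               # fraction of active genes sharing the causal variant
  effect_beta: [0.6, 0.15]   # |Normal(mean, sd)| per-allele effect, SD units
  noise_sd: 1.0              # residual expression SD
  snps_per_block: 8          # SNPs per LD block
  within_block_r2: 0.95      # target pairwise allelic r-squared within a block
  maf_range: [0.1, 0.5]      # per-block allele frequency range
  platform_snp_keep_i: 0.8   # fraction of panel SNPs genotyped by study i
  platform_snp_keep_j: 0.7   # ... and by study j (drawn independently)
  probe_overlap_frac: 0.8    # fraction of genes assayed on both platforms
  eqtl_gene_frac: 0.5        # fraction of genes with any eQTL
  n_haplotypes: 2000         # reference panel size (phased haplotypes)
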