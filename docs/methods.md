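# Methods

`eqtloverlap` estimates how often the genetic control of gene expression is
shared between two tissues from per-study cis-eQTL results. This note
describes the statistical procedure, the synthetic-data model used to
exercise it, the numerical choices, and the known limitations.

## The estimation problem

Two eQTL studies — a large "discovery" study *i* (think: a whole-blood
meta-analysis with thousands of samples) and a smaller "replication" study
*j* (think: a post-mortem brain cohort with one or two hundred samples) —
each report, per gene, the most significant cis SNP (eSNP) at a study-wide
FDR of 0.05. Three obstacles stand between those lists and the quantity of
interest, the fraction π of eQTL whose causal variant is shared:

1. **Different expression platforms.** Probes differ between arrays, so
   genes are first matched at the exon level: a gene enters the common
   universe only if each platform carries at least one probe whose interval
   is contained in the same annotated exon (0-based, half-open coordinates;
   among several qualifying probes the smallest-span one is used).
2. **Different SNP arrays.** The same causal variant is tagged by different
   genotyped SNPs in different studies, so direct eSNP-identity comparison
   is biased downwards. Each eSNP is therefore expanded into its proxy set —
   all reference-panel variants with haplotype-frequency
   r² = D²/(pA(1−pA)pB(1−pB)) above a threshold (default 0.8, sensitivity
   option 0.5) within ±100 kb — and two eSNPs overlap when their proxy sets
   intersect (an eSNP always contains itself; an alternative
   "eSNP_j ∈ proxies(eSNP_i)" criterion is exposed as a flag).
3. **Unequal power.** The observed overlap fraction
   π_raw = (# discovery eQTL genes overlapping in *j*) / (# discovery eQTL
   genes in the universe) underestimates π because study *j* misses true
   eQTL. The power-adjusted estimate is

       π_adjusted = (π_raw − a_j (1 − FDR_i)) / (power_j − a_j)        (1)
       power_j    = (power_j_raw − FDR_i · a_j) / (1 − FDR_i)          (2)

   where FDR_i is the discovery FDR level (0.05), a_j is the chance rate of
   the overlap event in study *j*, and power_j_raw is estimated by
   subsampling: repeatedly draw two mutually exclusive subsets of the
   discovery individuals, each of size n_j, call eQTL in both at the same
   study-wide FDR, and record the proportion of the first subset's eQTL
   whose best gene–eSNP association is itself significant in the second.
   The (1 − FDR_i) factors correct for false discoveries contaminating the
   discovery and first-subset lists.

### Choices inside the power procedure

- **Replication criterion.** "Also significant in the second subset" is
  scored by default at the eSNP level — the first subset's best gene–eSNP
  pair must itself be rejected in the second subset. This is the event whose
  probability is the slope-test power of that eSNP, which makes the
  estimate directly comparable to analytic noncentral-t power and keeps
  Eq. (2)'s false-discovery algebra exact. Gene-level (any significant cis
  SNP of the gene) and proxy-level (best eSNPs of the two subsets share an
  LD proxy) scoring are available via `match=`; gene-level scoring runs a
  few points above single-SNP power because a gene with ~k correlated cis
  SNPs gets k chances to clear the threshold.
- **Subsampling replicates.** The two-subset split is repeated (default 20
  replicates, seeded) and the mean and its standard error are reported; a
  single split would leave power_j_raw with a binomial error of several
  points.
- **Chance rate a_j.** Eq. (1) needs the probability that a non-shared
  discovery eQTL nonetheless counts as overlapping. Three estimators are
  provided. `realized_cutoff` (the standalone default): study *j*'s realized
  BH p-value cutoff, i.e. the chance a single null test is declared
  significant — the classical reading of a significance threshold α_j.
  `pair_rate`: the raw proportion of tested gene–SNP pairs significant in
  study *j*; note this conflates true positives with chance significance and
  grossly overstates a_j whenever study *j* has real signal, so it is kept
  only as a diagnostic. `override` with
  `harmonize.estimate_chance_overlap_rate`: a decoy estimate used by the
  pipeline — each discovery eQTL gene is paired with an unrelated
  common-universe gene (index shifted by half the universe) and the rate is
  the fraction of decoy pairs that would be called overlapping. The decoy
  estimate targets the chance rate of the *same event* π_raw counts (gene
  significant in *j* and proxy sets intersecting), which is typically an
  order of magnitude below the p-value cutoff; using the cutoff instead
  over-corrects and can push π_adjusted below π_raw when power is high.
- **Clipping.** Sampling noise can push Eqs. (1)–(2) outside [0, 1];
  estimates are clipped with a warning rather than erroring. power_j ≤ a_j
  raises an explicit undefined-estimate error.

### Chance expectation and enrichment

The chance expectation for two studies with eQTL proportions q_i and q_j
(fraction of common-universe genes with an eQTL) is their product q_i·q_j —
the null rate of gene-level co-occurrence when eQTL status is independent
across studies (e.g. 0.33 × 0.05 = 1.65%, quoted as 1.6% at table
precision). The enrichment test is a one-sided binomial upper tail
P(X ≥ k | n, q_i·q_j) with k the observed co-occurring genes and n the
common universe; that is the only pairing of the reported counts that lives
on the same scale as the chance product. Proxy-level π_raw is stricter than
co-occurrence, so under the null it sits at or below the chance product.

## The synthetic-data model

The generator emulates the study designs the estimator is meant for: two
studies of unequal size, overlapping but different SNP platforms, partially
overlapping probe sets, LD so that true eSNPs differ from genotyped proxies,
and a controlled true sharing fraction.

- **Panel.** N haplotypes (default 2000, a 1000-Genomes-scale panel) over
  `n_blocks` LD blocks of `snps_per_block` SNPs. Each block has one allele
  frequency drawn uniformly from `maf_range` (default 0.1–0.5, common
  variants typical of genotyping arrays). Haplotypes are built by a
  copy-with-noise scheme: per haplotype a latent founder allele
  z ~ Bernoulli(p); each site copies z with probability c and redraws
  Bernoulli(p) otherwise, giving expected allelic correlation c² between
  sites and hence pairwise r² = c⁴; c is set to `within_block_r2^(1/4)`
  (default target r² 0.95, dense-block LD so that 0.8-threshold proxy sets
  span the block). Blocks are independent; `within_block_r2 = 1` gives exact
  copies and 0 gives independent sites.
- **Layout.** Each gene owns a two-block locus: block A (causal variants
  for tissue *i* and for shared eQTL) centred on the TSS, block B 200 kb
  away — inside the ±1 Mb cis window but beyond the 100 kb proxy window, so
  tissue-specific eQTL can never proxy-match. Loci are spaced 1.5 Mb apart
  (cis windows never overlap a neighbouring locus), 500 per synthetic
  chromosome. Each gene has one 2 kb exon at the TSS; each platform's probe
  is a sub-interval of it.
- **Genetics and expression.** Individuals draw two panel haplotypes with
  replacement (Hardy–Weinberg, no population structure); expression is
  additive cis: y = β·dosage(causal) + Normal(0, noise_sd). Effect sizes are
  |Normal(0.6, 0.15)| in residual-SD units per allele — cis effects of top
  eSNPs are large and heterogeneous; this range gives intermediate
  single-study power at n ≈ 100–200 and near-complete power at n = 1000.
- **Sharing.** By default a gene is eQTL-active in both tissues or neither
  (`eqtl_gene_frac` = 0.5 of genes active), and among active genes a
  fraction `pi_true` shares the identical causal variant and effect size;
  non-shared genes draw tissue-*j* causal variants from block B with an
  independent β. `tissue_activity="independent"` instead draws per-tissue
  activity independently — the construction used for null calibration,
  where gene-level co-occurrence must equal the chance product exactly.
  `shared_beta_multiplier` scales shared effects only, deliberately
  violating the adjustment's equal-effect-size assumption for bias
  experiments (boosted shared effects inflate π_adjusted).
- **Platforms.** Each study genotypes an independent random fraction of
  panel variants (defaults 0.8 and 0.7 — array overlap in that range is
  typical) and assays `probe_overlap_frac` (default 0.8) of genes on both
  expression platforms, the remainder alternating.

What the generator does *not* model: coalescent-realistic LD decay,
population structure and cross-population LD differences, trans effects,
covariates/batch structure, cell-type mixtures, and overlapping cis windows
of neighbouring genes. Passing tests therefore demonstrate the estimator's
internal consistency under clean additive cis architecture, not robustness
to those real-data complications.

## Numerical and implementation notes

- The cis scan is closed-form simple regression, fully vectorised over all
  (gene, variant) pairs within the window (inclusive boundary at exactly
  the window size), with two-sided t tests at n − 2 df. Monomorphic
  variants and zero-variance genes are skipped with logged counts.
  Simulation sweeps may run the scan in float32 (`dtype=`), which perturbs
  t statistics by ~1e-4 relative — immaterial for FDR calls; the float64
  default matches `scipy.stats.linregress` to 1e-9 relative.
- BH-FDR is the textbook step-up over all tested gene–SNP pairs study-wide
  (the published studies' per-gene permutation thresholds are not
  reproducible from summary lists); the realized cutoff — the largest
  rejected p — is reported per study and doubles as the α_j estimate.
- Best-eSNP ties (equal p) break by smaller |distance to TSS|, then
  lexicographic variant id; the convention is arbitrary but deterministic.
- r² is computed from phased haplotype frequencies, not genotype
  correlation; monomorphic partners are excluded (LD undefined), and eSNPs
  absent from the panel degrade to self-only proxy sets with a warning.
- The proxy window is symmetric ±window_bp with inclusive bounds (a "100 kb"
  window reads as ±100 kb).
- Multi-cohort discovery studies are emulated by the sample-size-weighted
  Z combination Z = Σ√n_i·z_i / √(Σn_i).
- All randomness flows from explicit integer seeds; identical (config, seed)
  reproduces byte-identical simulations, reports and checksums.

## Problem sizes used in the shipped checks

The recovery sweep runs pi_true ∈ {0, 0.1, 0.2, 0.4} × n_j ∈ {100, 200}
with n_i = 1000, 2000 genes and 20 simulation replicates per cell, using 5
subsampling splits per power estimate (the per-pi_true mean already
averages 100 splits; the module default stays at 20). Null calibration uses
20 independent-activity replicates of 1000 genes plus one fully null
simulation of 5000 genes; power calibration uses a homogeneous-effect
design (β = 0.35, MAF 0.25–0.35, n_j = 150, 20 splits) where analytic
noncentral-t power is a clean oracle.

## Known limitations

- The subsampling procedure conditions on detection in the first subset, so
  with heterogeneous effect sizes power_j_raw estimates E[P²]/E[P] ≥ E[P];
  the residual downward bias in π_adjusted grows with effect-size variance
  and with π (about −0.02 at π = 0.4 under the default generator).
- Eq. (1) assumes shared and non-shared eQTL draw from the same effect-size
  distribution; violations bias π_adjusted in the direction of the shared
  effects (demonstrated, not corrected).
- The power estimate inherits the discovery platform; if the replication
  platform tags causal variants materially worse, power_j is optimistic and
  π_adjusted conservative.
- External (non-simulated) inputs are supported through eQTL summary lists
  plus a haplotype panel; power adjustment additionally needs the discovery
  study's raw genotype/expression matrices — without them only π_raw and
  the chance comparison are available.
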