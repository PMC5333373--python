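# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical conventions and the open design choices behind splicemap.

## Association model

PSI of event *e* is regressed on the allele dosage of SNP *s* with an
intercept and covariates:

PSI_e = mu + beta * g_s + gamma' C + eps, eps ~ N(0, sigma^2).

* Cis universe: all pairs with gap distance strictly < `window_bp`
  (default 100,000 bp). The gap is 0 when the SNP lies inside the event
  span, else the distance to the nearer span end; coordinates are 1-based
  inclusive in memory and in TSVs, converted to 0-based half-open only at
  BED boundaries. An `window_inclusive` flag flips the boundary to <=
  for users who read "±100 kb" inclusively.
* Missing data: dosages are mean-imputed per SNP across all samples
  before any regression (the Matrix-eQTL convention); samples with
  missing PSI are dropped pairwise. Pairs with fewer than 10 usable
  samples, or zero dosage variance after imputation, are skipped and
  counted.
* Inference: two-sided p from the t distribution with n − k − 2 residual
  degrees of freedom (intercept + genotype + k covariate columns), not a
  normal approximation — exactness at n ≈ 200 costs nothing. Constant
  PSI returns beta = 0, p = 1. Rank-deficient covariate columns are
  greedily pruned with a warning.
* Implementation: the hot path residualises PSI and the dosage block on
  the covariate design via QR (Frisch–Waugh), which is algebraically the
  full OLS fit; the per-pair entry point solves the design directly. Both
  are tested against an explicit normal-equations oracle at 1e-10
  relative tolerance.

## Double correction and sQTL calls

BH adjustment is computed once across the complete cis pair list (adjusting
per chunk is provably different and a counter-example test documents it).
Per SNP, the smallest adjusted p is multiplied by the number of retained
AS events within the SNP's window — counted from the filtered event table,
not from the tested pairs, so an event whose specific pair was skipped
still contributes to the multiplier — capped at 1. `is_sqtl` means
p_double < alpha (default 0.05, exposed as a flag). The best pair per SNP
and the best sQTL SNP per event break ties deterministically: smaller p,
then smaller distance, then lexicographic ID.

## QC filters

Event filters run in a fixed order. (1) Quality: drop events whose
per-sample quality flag fails in strictly more than 20% of samples (the
flag stands in for the read-coverage score of a vast-tools combine table;
missing PSI counts as a failed flag). (2) Degeneracy: drop events whose
PSI equals exactly 0 or 100 in strictly more than 90% of the samples with
an observed PSI — missing values are excluded from the denominator because
real PSI tables have per-sample coverage gaps. The audit table partitions
the input: retained + failed_quality + degenerate. SNP filter: MAF >= 1%
(recomputed on the intersected analysis sample set) and gap < 100 kb to
the nearest retained event.

## LD, pruning, comparison sets

* r² is the squared Pearson correlation of unphased dosage vectors over
  pairwise-complete samples — close to PLINK's composite estimator and
  needing no phasing. Zero variance makes LD undefined (error).
* Pruning follows the indep-pairwise scheme (window 50 SNPs, step 5,
  threshold r² > 0.5). Within a window, the currently highest-r² offending
  pair loses its lower-MAF member (MAF tie: later position) — a
  deterministic emulation of PLINK's preference for keeping the more
  informative SNP; only the three parameters are fixed by convention. The
  postcondition (no surviving within-window pair with r² > 0.5) is
  verified exhaustively in tests.
* Non-sQTL universe: SNPs whose smallest uncorrected local p is strictly
  above 0.05, then pruned identically.
* MAF matching uses bins [0, 0.02), …, [0.48, 0.50]. With scaling factor
  s = min over occupied sQTL bins of (controls in bin / sQTLs in bin), the
  global budget floor(s × n_sqtl) is allocated per bin by floor plus a
  largest-remainder top-up and sampled without replacement under the run
  seed. This proportional-scaling rule is one consistent reading of
  "matched distribution"; capping at the smallest bin ratio guarantees
  feasibility. On small synthetic panels a lone pruned sQTL occasionally
  lands in a MAF bin with no control candidate; `match_maf` itself raises
  (naming the bin), while the pipeline drops such unmatchable sQTLs from
  the comparison sets with a warning.

## Enrichment

Functional classes form a fixed 13-label precedence order (nonsense …
non-coding exon, intron, intergenic); a multi-labelled SNP takes the
highest-impact (leftmost) label and unlabelled SNPs default to intergenic.
The per-class family tests 10 types (the four loss-of-function classes
pooled), each Bonferroni-corrected by 10; the pooled exonic-vs-rest test
is its own family of one. Regulatory tracks are tested by point-in-interval
membership (SNP pos − 1 in the 0-based half-open BED interval); the
element family is corrected by the number of element tracks and the TF
family by the number of TFs retained after the >= 50,000-record inclusion
rule. Track objects carry the source record count explicitly because a
synthetic chromosome cannot host ENCODE-scale record numbers; the
synthetic pipeline passes `tf_min_records=0` and the threshold logic is
unit-tested with explicit counts. Disease-locus tests are one-tailed
(greater), with a 15-trait family correction and an optional MHC mask
(chr6:28,477,797–33,448,354 inclusive) applied to both sets; subsets
restrict to exonic, non-exonic (intron + intergenic) or non-IR-best sQTLs.

Odds ratios are sample cross-product ratios with a Haldane–Anscombe +0.5
on all cells only when a zero cell occurs; 95% CIs use the Woolf logit
interval on the corrected table. The conditional-MLE OR (as R's
fisher.test reports) is available via `estimator="conditional-mle"`; the
cross-product form is the default because it is the simplest reproducible
convention. Two-tailed p-values sum all hypergeometric tables at the
observed margins with probability <= the observed table (scipy's
convention, verified against exact rational enumeration at 1e-12).

## Risk-locus triage

A locus interval is the span of SNPs with r² strictly > 0.6 to the index
SNP (singleton when none). When a declared index SNP is absent from the
LD reference, the most significant locus SNP present in the reference
substitutes (ties: earlier position, then ID). A candidate record requires
all three criteria — r² > 0.8 to the index, own GWAS p < 5e-8, credible-set
membership — each strict, each individually necessary (tested by
relaxation). One record is emitted per (locus, sQTL SNP) with the SNP's
best-associated event; all qualifying SNPs are reported and ranked by
p_double rather than suppressing secondary hits. The LD reference defaults
to the analysis genotype panel itself; a real study would pass an external
reference panel.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale:

* **Genotypes.** SNPs at strictly increasing positions on one chromosome,
  grouped into blocks of `ld_block_size`. Haplotype alleles are
  thresholded latent Gaussians, sqrt(rho)·z_block + sqrt(1−rho)·eps <
  Phi⁻¹(MAF); dosage is the sum of two haplotypes. SNPs within a block
  share a block-level target MAF (±5% jitter) drawn from `maf_range`, so
  the dichotomised haplotypes retain most of the latent correlation.
  Dichotomisation still attenuates: latent rho 0.9 realises mean dosage
  r² ≈ 0.5 and rho 0.97 ≈ 0.7. `within_block_rho` is therefore a monotone
  LD dial, not the realised r² itself.
* **PSI.** Latent PSI = baseline (uniform in `baseline_psi_range`,
  default 20–80) + beta·dosage for the planted pairs + covariate terms +
  N(0, noise_sd), clipped to [0, 100]. Gaussian-plus-clipping (rather than
  logit-normal) is chosen deliberately: it matches the additive linear
  model that is actually fitted, and the clipping bound is exercised in
  tests. All planted betas equal `effect_size_psi` with positive sign so
  the genotype-stratified report has a testable monotone mean. Each causal
  event's span is re-positioned inside its SNP's cis window; covariates
  are two continuous confounders (age-like, RIN-like; standardised before
  applying their PSI-unit effects) and a 3-level site factor encoded as
  drop-first indicators.
* **Quality structure.** Most events fail their per-sample quality flag
  at rate 2%; 5% of non-causal events fail at 35% (removed by the >20%
  rule) and 3% are degenerate (PSI pinned at 0 in ~95% of samples), so
  both QC filters have work to do. 1% of PSI entries are missing.
* **Annotations and GWAS.** Functional labels follow a genome-like mix
  (~87% intron/intergenic); three element tracks and three TF tracks are
  uniform random intervals. A fraction `frac_causal_in_gwas_loci` of
  causal SNPs is planted inside risk loci: the index SNP is the
  highest-r² block-mate above 0.8 (the causal SNP itself when none — the
  direct analogue of an index SNP that is its own sQTL), the locus spans
  the r² > 0.6 neighbourhood, the credible set holds index and causal
  SNP, and both receive genome-wide-significant summary p-values; all
  other SNPs get p ~ U(0.05, 1). Decoy loci are placed in SNP-free gaps.
* **Determinism.** All randomness flows from `seed` through a fixed
  four-way SeedSequence split (genotypes / covariates / PSI /
  annotations+GWAS); identical configs give byte-identical files.

What the generator does **not** emulate: read-level sampling noise in PSI
(beta-binomial overdispersion), realistic splicing-code sequence features,
population structure and relatedness, phased haplotypes, and ENCODE-scale
annotation density. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative model, not performance
on real cohort data, where LD, PSI noise and confounding are richer.

## Problem sizes and defaults

Defaults mirror a single-cohort brain study scaled to desk size: 206
samples, 2,000 SNPs and 200 events on a 20-Mb chromosome, 20 planted
effects of 8 PSI units against noise SD 5. The test suite and the
acceptance script use 150–250 samples, 1,000–2,000 SNPs, 120–200 events
and 10–20 seeds per property; at these sizes the full suite runs in well
under a minute per property while leaving the Monte-Carlo margins (e.g.
>= 80% recall, <= 5% null call rate) comfortably wide.

## Known limitations

* The BH-then-local-Bonferroni correction is conservative by
  construction; its empirical null call rate is near zero rather than 5%.
* LD pruning is greedy and order-dependent across windows, as in the
  conventional tool it emulates; only the postcondition is guaranteed.
* Locus expansion scans every SNP on the index's chromosome (quadratic in
  panel size if applied to all loci of a dense panel); adequate at desk
  scale.
* The Woolf CI is approximate for sparse tables even with the +0.5
  correction; the exact conditional CI is not implemented.
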