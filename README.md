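# splicemap

Genome-wide *cis* splicing-QTL (sQTL) mapping for bulk RNA-seq studies:
association of SNP dosages with percent-spliced-in (PSI) of alternative-
splicing events, a two-layer multiple-testing correction for calling sQTL
SNPs, construction of LD-pruned sQTL and MAF-matched non-sQTL comparison
sets, Fisher-exact enrichment against functional classes, regulatory
annotations and GWAS risk loci, and LD/credible-set triage of candidate
disease genes. A first-class synthetic-data generator plants known cis
effects so every stage is testable end to end with no external data.

It is written for statistical geneticists and computational biologists who
have a PSI table (vast-tools-style), a genotype dosage table (TSV or VCF)
and per-sample covariates, and who want the full chain from per-pair
regression to per-locus candidate-gene nomination as a reusable library.

## The model

For each AS event *e* and SNP *s* whose gap distance is below 100 kb, PSI
is fitted by ordinary least squares under the additive model

> PSI_e = mu + beta * g_s + gamma' C + epsilon,  epsilon ~ N(0, sigma^2)

with dosage g in {0, 1, 2} (missing dosages mean-imputed, missing PSI
dropped pairwise) and covariate matrix C. Two-sided p-values use the t
distribution with n − k − 2 degrees of freedom.

Calling sQTL SNPs uses the **double correction**: Benjamini–Hochberg over
the complete pair list, then per SNP

> p_double = min(1, min_e BH(p_{s,e}) × N_s),

where N_s counts the filtered AS events within ±100 kb of SNP *s*. A SNP
is an sQTL when p_double < 0.05 — a SNP surrounded by many events must
clear a proportionally higher bar.

Downstream, the best sQTL SNP per event is LD-pruned (sliding window of 50
SNPs, step 5, r² > 0.5 removed), compared against non-sQTL SNPs (smallest
uncorrected p > 0.05, same pruning) matched on the MAF histogram in 2%
bins, and tested for enrichment with Fisher's exact test (two-tailed for
functional classes and regulatory tracks, one-tailed for disease loci,
Bonferroni-corrected within each test family). Risk-locus triage nominates
sQTL SNPs in LD with a locus index SNP at r² > 0.8 that are genome-wide
significant themselves (p < 5×10⁻⁸) and belong to the locus credible set.

## Worked example

```python
from splicemap import SimConfig, run_pipeline

res = run_pipeline(SimConfig(n_samples=206, n_snps=2000, n_events=200,
                             n_causal=20, frac_causal_in_gwas_loci=1.0, seed=1))
print(res.counts)
```

The run above prints (abridged; see `examples/` for the narrative
versions):

```
event QC: 184/200 retained (10 failed quality, 6 degenerate)
SNP universe: 1712/2000 with MAF >= 1% near a retained event
3700 cis pairs tested -> 185 sQTL SNPs (double-corrected p < 0.05), best SNP for 60 events
planted causal SNPs recovered: 20/20
pruned sQTL set: 42 SNPs (from 60 best-per-event SNPs)
non-sQTL universe: 1356 SNPs with min p > 0.05, 600 after pruning, 136 MAF-matched controls
locus enrichment: a=19 b=23 c=0 d=136 OR=226.53 one-tailed p=2.57e-14
```

All 20 planted effects (beta = 8 PSI units per allele against noise SD 5)
are recovered as sQTLs; with every causal SNP planted inside a GWAS locus
the one-tailed locus test is overwhelmingly enriched, and triage nominates
one candidate per planted locus with the true event attached. The
`psi_by_genotype` report shows the additive effect directly: mean PSI
78.8 → 88.0 → 95.5 across dosage 0/1/2 for the top candidate.

A thin CLI mirrors the library:
`splicemap simulate|filter|map|sets|enrich|triage|run` (see `--help`).

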