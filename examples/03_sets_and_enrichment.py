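"""Build the pruned sQTL / MAF-matched control sets and test enrichment.

The sQTL side is the best SNP per event after 50/5/0.5 LD pruning; the
control side is drawn from LD-pruned SNPs whose smallest uncorrected p
exceeds 0.05, matched to the sQTL minor-allele-frequency histogram in 2%
bins. Fisher's exact test then compares functional-class and regulatory-
element membership between the two sets.
"""

from splicemap import SimConfig, run_pipeline

res = run_pipeline(SimConfig(n_samples=206, n_snps=2000, n_events=200, n_causal=20, seed=1))
c = res.counts

print(f"pruned sQTL set: {c['n_sqtl_pruned']} SNPs "
      f"(from {c['n_best_per_event']} best-per-event SNPs)")
print(f"non-sQTL universe: {c['n_nonsqtl_universe']} SNPs with min p > 0.05, "
      f"{c['n_nonsqtl_pruned']} after pruning, {c['n_matched_controls']} MAF-matched controls")

print("\nfunctional enrichment (two-tailed Fisher, 10-type family):")
for r in res.enrichment_functional:
    flag = "*" if r.p_adj < 0.05 else " "
    print(f"  {flag} {r.test_name:22s} OR={r.odds_ratio:6.2f} p={r.p:9.3g} p_adj={r.p_adj:.3g}")

print("\nregulatory elements / TF binding sites:")
for r in res.enrichment_intervals:
    print(f"    {r.test_name:10s} OR={r.odds_ratio:6.2f} p={r.p:9.3g} (family of {r.family_size})")
# On neutral synthetic annotations the ORs hover around 1; a planted
# association (e.g. sQTLs concentrated in exonic classes) moves the OR away
# from 1 and the adjusted p below 0.05.
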