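"""Generate one synthetic brain-sQTL study and look at its pieces.

The generator plants additive cis effects (beta PSI-units per alt allele)
for a chosen number of SNP-event pairs, confounds PSI with covariates and
wraps everything in the on-disk formats the pipeline consumes.
"""

from splicemap import SimConfig, simulate_dataset

config = SimConfig(
    n_samples=206,      # study-sized cohort
    n_snps=2000,
    n_events=200,
    n_causal=20,        # planted sQTLs
    effect_size_psi=8.0,  # PSI units per alt allele
    noise_sd=5.0,
    seed=1,
)
ds = simulate_dataset(config)

print(f"genotypes: {ds.genotypes.n_snps} SNPs x {len(ds.genotypes.samples)} samples")
print(f"MAF range: {ds.genotypes.snps['maf'].min():.3f}-{ds.genotypes.snps['maf'].max():.3f}")
print(f"events: {ds.events.n_events} ({ds.events.events['as_type'].value_counts().to_dict()})")
print(f"planted causal pairs: {len(ds.truth.causal_snp_ids)}")
print(f"GWAS loci: {len(ds.gwas.loci)} "
      f"({(ds.gwas.loci['index_snp'] != '').sum()} planted, rest decoys in SNP-free gaps)")
first = ds.truth.causal_snp_ids[0]
print(f"example planted sQTL: {first} -> {ds.truth.causal_event_ids[0]} "
      f"(beta = {ds.truth.planted_betas[0]} PSI/allele)")
# The AS-type mix, LD-block genotypes and bounded noisy PSI mimic what a
# rRNA-depleted brain RNA-seq + SNP-array study would feed the pipeline.
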