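"""Synthetic data generator for the sQTL pipeline.

Emulates, at desk scale, the statistical structure of the inputs the
analysis assumes: block-LD SNP dosages with a stated MAF spectrum, PSI
tables with additive planted cis effects plus covariate confounding and
bounded noise, per-sample quality flags, functional/regulatory annotation
tracks, and GWAS panels whose risk loci, index SNPs and credible sets
overlap a controllable fraction of the planted causal sQTLs.

Generative model
----------------
Genotypes: SNPs sit on one chromosome at strictly increasing positions and
are grouped into consecutive LD blocks. Each haplotype allele is a
thresholded latent Gaussian, ``sqrt(rho) * z_block + sqrt(1-rho) * eps <
Phi^{-1}(maf)``, so within-block haplotypes share correlation ``rho`` and
between-block SNPs are independent; dosage is the sum of two haplotypes.

PSI: latent PSI = baseline + beta * dosage (causal pairs only)
+ covariate terms + N(0, noise_sd), then clipped to [0, 100]. Each causal
event's genomic span is placed within the cis window of its causal SNP.

All randomness flows from ``SimConfig.seed`` through a fixed stream-splitting
scheme, so an identical config reproduces byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import child_rngs, gap_distance
from .types import (
    AS_TYPES,
    ASEventTable,
    AnnotationSet,
    CovariateTable,
    GenotypeMatrix,
    GWASPanel,
    InvalidConfigError,
    Track,
    TruthTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_psi",
    "simulate_annotations_and_gwas",
    "simulate_dataset",
]

# 13-class functional vocabulary, highest impact first (exonic classes then
# intron/intergenic); kept in sync with enrichment.FUNCTIONAL_CLASSES.
_FUNCTIONAL_LABELS = (
    "nonsense",
    "readthrough",
    "start-loss",
    "frameshift",
    "canonical splice site",
    "missense",
    "synonymous",
    "splice region",
    "5'-UTR",
    "3'-UTR",
    "non-coding exon",
    "intron",
    "intergenic",
)
# Rough genome-wide mix for a SNP array panel: mostly intronic/intergenic.
_FUNCTIONAL_PROBS = (
    0.0005,
    0.0005,
    0.0005,
    0.0005,
    0.001,
    0.012,
    0.012,
    0.004,
    0.008,
    0.025,
    0.016,
    0.47,
    0.45,
)

# AS-type mix close to a rRNA-depleted brain RNA-seq event table: intron
# retention dominates, then exon skipping, then alternative splice sites.
_AS_TYPE_PROBS = {"AltEX": 0.285, "AltSS5": 0.012, "AltSS3": 0.020, "IR": 0.683}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study design the pipeline targets at desk scale:
    206 post-mortem brain samples, array-genotyped SNPs on one chromosome
    with block LD, PSI effects of several PSI-units per alt allele, and a
    covariate set with two continuous confounders and a 3-level site factor.
    """

    n_samples: int = 206
    n_snps: int = 2000
    n_events: int = 200
    chrom: str = "chr1"
    chrom_length: int = 20_000_000
    ld_block_size: int = 10
    within_block_rho: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 20
    effect_size_psi: float = 8.0
    noise_sd: float = 5.0
    covariate_effects: tuple[float, ...] = (2.0, -1.5, 3.0, -3.0)
    frac_causal_in_gwas_loci: float = 0.5
    seed: int = 0

    # Generator-only knobs (kept out of the headline parameters above).
    baseline_psi_range: tuple[float, float] = (20.0, 80.0)
    event_span_range: tuple[int, int] = (150, 3000)
    cis_window_bp: int = 100_000
    quality_fail_rate: float = 0.02
    quality_bad_event_frac: float = 0.05
    quality_bad_event_fail_rate: float = 0.35
    degenerate_event_frac: float = 0.03
    psi_missing_rate: float = 0.01
    n_decoy_gwas_loci: int = 3
    gwas_locus_r2: float = 0.6

    def validate(self) -> None:
        if self.n_samples < 2:
            raise InvalidConfigError("n_samples must be >= 2")
        for name in ("n_snps", "n_events", "chrom_length", "ld_block_size"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidConfigError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.within_block_rho < 1.0):
            raise InvalidConfigError("within_block_rho must be in [0, 1)")
        if not (0.0 <= self.frac_causal_in_gwas_loci <= 1.0):
            raise InvalidConfigError("frac_causal_in_gwas_loci must be in [0, 1]")
        if self.n_causal < 0 or self.n_causal > min(self.n_snps, self.n_events):
            raise InvalidConfigError("n_causal must be in [0, min(n_snps, n_events)]")
        if self.frac_causal_in_gwas_loci > 0 and self.n_causal == 0:
            raise InvalidConfigError("frac_causal_in_gwas_loci > 0 requires n_causal > 0")
        if not np.isfinite([self.effect_size_psi, self.noise_sd]).all():
            raise InvalidConfigError("effect sizes must be finite")
        if self.n_snps > self.chrom_length:
            raise InvalidConfigError("more SNPs than positions on the chromosome")


@dataclass
class SimulatedDataset:
    """Bundle of everything one simulated study comprises."""

    config: SimConfig
    genotypes: GenotypeMatrix
    covariates: CovariateTable
    events: ASEventTable
    truth: TruthTable
    annotations: AnnotationSet
    gwas: GWASPanel


def _stream(config: SimConfig, index: int) -> np.random.Generator:
    # Fixed stream assignment: 0 genotypes, 1 covariates, 2 psi, 3 annotations/gwas.
    return child_rngs(config.seed, 4)[index]


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Block-LD dosage panel on one chromosome.

    Dosages are in {0, 1, 2}; adjacent SNPs within a block of
    ``ld_block_size`` share latent haplotype correlation ``within_block_rho``
    and SNPs in different blocks are independent.
    """
    config.validate()
    rng = _stream(config, 0)
    n, m = config.n_samples, config.n_snps

    pos = np.sort(rng.choice(config.chrom_length, size=m, replace=False)) + 1
    block_of = np.arange(m) // config.ld_block_size
    n_blocks = block_of[-1] + 1
    # Blocks share a target MAF (small per-SNP jitter): equal thresholds keep
    # the dichotomised haplotypes close to the latent correlation, so
    # within_block_rho behaves as a usable LD dial.
    block_maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=n_blocks)
    jitter = rng.uniform(0.95, 1.05, size=m)
    mafs = np.clip(block_maf[block_of] * jitter, config.maf_range[0], config.maf_range[1])
    thresholds = stats.norm.ppf(mafs)
    rho = config.within_block_rho

    dosage = np.zeros((n, m), dtype=float)
    for _hap in range(2):
        z_block = rng.standard_normal((n, n_blocks))
        eps = rng.standard_normal((n, m))
        latent = np.sqrt(rho) * z_block[:, block_of] + np.sqrt(1.0 - rho) * eps
        dosage += latent < thresholds[None, :]

    alleles = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4

    snp_ids = [f"rs{i:06d}" for i in range(1, m + 1)]
    samples = [f"S{i:04d}" for i in range(1, n + 1)]
    snps = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": pos.astype(np.int64),
            "ref": alleles[ref_idx],
            "alt": alleles[alt_idx],
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    dosage_df = pd.DataFrame(dosage.T, index=snps.index, columns=samples)
    geno = GenotypeMatrix(snps, dosage_df)
    geno.recompute_maf()
    return geno


def simulate_covariates(config: SimConfig) -> CovariateTable:
    """Two continuous confounders (age-like, RIN-like) and a 3-level site factor."""
    config.validate()
    rng = _stream(config, 1)
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(1, n + 1)]
    df = pd.DataFrame(
        {
            "age_death": np.round(rng.normal(70.0, 15.0, size=n), 1),
            "rin": np.round(np.clip(rng.normal(7.5, 1.0, size=n), 2.0, 10.0), 2),
            "institute": rng.choice(["MSSM", "Penn", "Pitt"], size=n),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return CovariateTable(df)


def _covariate_psi_terms(config: SimConfig, covariates: CovariateTable) -> np.ndarray:
    """Per-sample covariate contribution to latent PSI, in PSI units.

    Continuous covariates are standardised before multiplying by their
    effect so covariate_effects reads as PSI units per covariate SD.
    """
    design, names = covariates.design_matrix()
    effects = np.asarray(config.covariate_effects, dtype=float)
    if len(effects) != design.shape[1]:
        raise InvalidConfigError(
            f"covariate_effects has length {len(effects)} but the covariate design "
            f"has {design.shape[1]} columns ({names})"
        )
    design = design.copy()
    for j, name in enumerate(names):
        if "[" not in name:  # continuous column: standardise
            sd = design[:, j].std()
            if sd > 0:
                design[:, j] = (design[:, j] - design[:, j].mean()) / sd
    return design @ effects


def simulate_psi(
    config: SimConfig, genotypes: GenotypeMatrix, covariates: CovariateTable
) -> tuple[ASEventTable, TruthTable]:
    """PSI table with planted additive cis effects and quality flags."""
    config.validate()
    if list(genotypes.samples) != list(covariates.samples):
        raise InvalidConfigError("genotypes and covariates must share sample IDs in order")
    rng = _stream(config, 2)
    n, n_ev = config.n_samples, config.n_events

    event_ids = [f"EV{i:05d}" for i in range(1, n_ev + 1)]
    genes = [f"GENE{i:05d}" for i in range(1, n_ev + 1)]
    as_types = rng.choice(
        list(_AS_TYPE_PROBS), size=n_ev, p=list(_AS_TYPE_PROBS.values())
    )

    causal_events = rng.choice(n_ev, size=config.n_causal, replace=False)
    causal_snps = rng.choice(config.n_snps, size=config.n_causal, replace=False)
    snp_pos = genotypes.snps["pos"].to_numpy()

    widths = rng.integers(config.event_span_range[0], config.event_span_range[1] + 1, size=n_ev)
    starts = rng.integers(1, max(2, config.chrom_length - widths.max()), size=n_ev)
    # Causal events are re-positioned inside the cis window of their SNP so
    # the planted pair is always testable (gap strictly < cis_window_bp).
    max_offset = config.cis_window_bp // 2
    for ev_i, snp_i in zip(causal_events, causal_snps):
        offset = rng.integers(-max_offset, max_offset + 1)
        start = int(np.clip(snp_pos[snp_i] + offset, 1, config.chrom_length - widths[ev_i]))
        starts[ev_i] = start
    ends = starts + widths - 1

    baseline = rng.uniform(*config.baseline_psi_range, size=n_ev)
    cov_terms = _covariate_psi_terms(config, covariates)

    beta = np.zeros(n_ev)
    beta[causal_events] = config.effect_size_psi
    dosage = genotypes.dosage.to_numpy()  # (snps, samples)

    latent = baseline[:, None] + cov_terms[None, :] + rng.normal(0.0, config.noise_sd, size=(n_ev, n))
    for ev_i, snp_i in zip(causal_events, causal_snps):
        latent[ev_i] += config.effect_size_psi * dosage[snp_i]

    out_of_range = ((latent < 0) | (latent > 100)).mean(axis=1)
    worst = out_of_range.max(initial=0.0)
    if worst > 0.5:
        logger.warning(
            "planted effects push latent PSI outside [0, 100] for %.0f%% of samples "
            "in the worst event; clipping applied",
            100 * worst,
        )
    psi = np.clip(latent, 0.0, 100.0)

    # Quality flags: most events fail rarely; a small set of "bad" events
    # fails often enough to be dropped by the >20% rule downstream.
    causal_set = set(causal_events.tolist())
    non_causal = np.array([i for i in range(n_ev) if i not in causal_set], dtype=int)
    fail_rate = np.full(n_ev, config.quality_fail_rate)
    n_bad = int(round(config.quality_bad_event_frac * n_ev))
    n_degen = int(round(config.degenerate_event_frac * n_ev))
    special = rng.choice(non_causal, size=min(len(non_causal), n_bad + n_degen), replace=False)
    bad_events, degen_events = special[:n_bad], special[n_bad : n_bad + n_degen]
    fail_rate[bad_events] = config.quality_bad_event_fail_rate
    quality_ok = rng.random((n_ev, n)) >= fail_rate[:, None]

    # Degenerate events: PSI pinned at 0 in almost all samples.
    for ev_i in degen_events:
        psi[ev_i] = 0.0
        lift = rng.random(n) < 0.05
        psi[ev_i, lift] = rng.uniform(1.0, 30.0, size=lift.sum())

    missing = rng.random((n_ev, n)) < config.psi_missing_rate
    psi[missing] = np.nan
    quality_ok &= ~missing

    events = pd.DataFrame(
        {
            "gene": genes,
            "as_type": as_types,
            "chrom": config.chrom,
            "span_start": starts.astype(np.int64),
            "span_end": ends.astype(np.int64),
        },
        index=pd.Index(event_ids, name="event_id"),
    )
    samples = genotypes.samples
    table = ASEventTable(
        events,
        pd.DataFrame(psi, index=events.index, columns=samples),
        pd.DataFrame(quality_ok, index=events.index, columns=samples),
    )
    order = np.argsort(causal_events)
    truth = TruthTable(
        causal_snp_ids=[genotypes.snps.index[causal_snps[i]] for i in order],
        causal_event_ids=[event_ids[causal_events[i]] for i in order],
        planted_betas=[float(beta[causal_events[i]]) for i in order],
    )
    return table, truth


def _empirical_r2_to(dosage: np.ndarray, j: int) -> np.ndarray:
    """r^2 of every SNP row against row j (no missing values expected here)."""
    x = dosage[j]
    xc = x - x.mean()
    denom_x = (xc**2).sum()
    yc = dosage - dosage.mean(axis=1, keepdims=True)
    denom_y = (yc**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ xc) / np.sqrt(denom_y * denom_x)
    return np.nan_to_num(r) ** 2


def simulate_annotations_and_gwas(
    config: SimConfig, genotypes: GenotypeMatrix, truth: TruthTable
) -> tuple[AnnotationSet, GWASPanel]:
    """Functional labels, regulatory tracks and a GWAS panel with planted loci.

    A fraction ``frac_causal_in_gwas_loci`` of planted causal SNPs is placed
    inside risk loci whose index SNP is the highest-LD block-mate (the causal
    SNP itself when no block-mate exceeds r^2 = 0.8) and whose credible set
    contains both the index and the causal SNP. Decoy loci are placed in
    SNP-free gaps of the chromosome.
    """
    config.validate()
    if config.frac_causal_in_gwas_loci > 0 and len(truth.causal_snp_ids) == 0:
        raise InvalidConfigError("frac_causal_in_gwas_loci > 0 requires planted causal SNPs")
    rng = _stream(config, 3)
    snp_ids = list(genotypes.snps.index)
    pos = genotypes.snps["pos"].to_numpy()
    dosage = genotypes.dosage.to_numpy()

    # Functional labels: one primary label per SNP, occasionally a second.
    primary = rng.choice(
        _FUNCTIONAL_LABELS, size=len(snp_ids), p=np.asarray(_FUNCTIONAL_PROBS) / sum(_FUNCTIONAL_PROBS)
    )
    rows = [(sid, lab) for sid, lab in zip(snp_ids, primary)]
    extra_mask = rng.random(len(snp_ids)) < 0.10
    extra_labels = rng.choice(_FUNCTIONAL_LABELS, size=extra_mask.sum())
    for sid, lab in zip(np.asarray(snp_ids, dtype=object)[extra_mask], extra_labels):
        rows.append((sid, lab))
    functional = pd.DataFrame(rows, columns=["snp_id", "label"]).sort_values(
        ["snp_id", "label"], ignore_index=True
    )

    # Regulatory tracks: uniform random intervals.
    tracks: dict[str, Track] = {}
    for name, family in [
        ("DHS", "element"),
        ("H3K4me1", "element"),
        ("H3K4me3", "element"),
        ("POLR2A", "tf"),
        ("PHF8", "tf"),
        ("SIN3A", "tf"),
    ]:
        n_iv = 200
        lengths = rng.integers(500, 2000, size=n_iv)
        starts0 = rng.integers(0, config.chrom_length - int(lengths.max()), size=n_iv)
        iv = (
            pd.DataFrame({"chrom": config.chrom, "start": starts0, "end": starts0 + lengths})
            .sort_values(["start", "end"], ignore_index=True)
        )
        tracks[name] = Track(name=name, family=family, intervals=iv)

    # GWAS panel.
    n_planted = int(round(config.frac_causal_in_gwas_loci * len(truth.causal_snp_ids)))
    chosen = list(rng.permutation(len(truth.causal_snp_ids))[:n_planted])
    summary_p = rng.uniform(0.05, 1.0, size=len(snp_ids))
    snp_index = {s: i for i, s in enumerate(snp_ids)}
    block_of = np.arange(len(snp_ids)) // config.ld_block_size

    loci_rows, credible_rows, overlaps = [], [], []
    for k, truth_i in enumerate(sorted(chosen)):
        causal_id = truth.causal_snp_ids[truth_i]
        ci = snp_index[causal_id]
        r2 = _empirical_r2_to(dosage, ci)
        mates = np.where((block_of == block_of[ci]) & (np.arange(len(snp_ids)) != ci))[0]
        strong = mates[r2[mates] > 0.8]
        if len(strong):
            idx_i = int(strong[np.argmax(r2[strong])])
        else:
            idx_i = ci
        r2_idx = _empirical_r2_to(dosage, idx_i)
        members = np.where(r2_idx > config.gwas_locus_r2)[0]
        members = np.union1d(members, [idx_i, ci])
        start = int(pos[members].min()) - 1000
        end = int(pos[members].max()) + 1000
        locus_id = f"L{k + 1:03d}"
        loci_rows.append((locus_id, config.chrom, max(1, start), end, snp_ids[idx_i]))
        for m in sorted({idx_i, ci}):
            credible_rows.append((locus_id, snp_ids[m]))
        # Genome-wide significant signal at the index and the causal SNP.
        for m in {idx_i, ci}:
            summary_p[m] = 10.0 ** rng.uniform(-15.0, -8.5)
        overlaps.append((causal_id, locus_id))

    # Decoy loci inside SNP-free gaps.
    gaps = np.diff(pos)
    gap_order = np.argsort(gaps)[::-1]
    n_decoys = min(config.n_decoy_gwas_loci, (gaps > 4000).sum())
    for d in range(n_decoys):
        g = gap_order[d]
        centre = (pos[g] + pos[g + 1]) // 2
        half = min(1000, (gaps[g] - 2) // 2 - 1)
        locus_id = f"D{d + 1:03d}"
        loci_rows.append((locus_id, config.chrom, int(centre - half), int(centre + half), ""))

    summary = pd.DataFrame(
        {"snp": snp_ids, "chrom": config.chrom, "pos": pos, "p": summary_p}
    )
    loci = pd.DataFrame(
        loci_rows, columns=["locus_id", "chrom", "start", "end", "index_snp"]
    )
    credible = pd.DataFrame(credible_rows, columns=["locus_id", "snp"])
    truth.planted_locus_overlaps = overlaps
    return AnnotationSet(functional, tracks), GWASPanel(summary, loci, credible)


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate one complete synthetic study."""
    genotypes = simulate_genotypes(config)
    covariates = simulate_covariates(config)
    events, truth = simulate_psi(config, genotypes, covariates)
    annotations, gwas = simulate_annotations_and_gwas(config, genotypes, truth)
    return SimulatedDataset(config, genotypes, covariates, events, truth, annotations, gwas)
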