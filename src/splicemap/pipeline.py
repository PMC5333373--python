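"""End-to-end orchestration: simulate -> filter -> map -> sets -> enrich -> triage.

The single entry point :func:`run_pipeline` chains every stage on an
in-memory dataset and returns all intermediate and final products, logging
the filter counts along the way. The CLI and the examples are thin
wrappers around it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import enrichment, filtering, ldsets, mapping, triage
from .simulate import SimConfig, SimulatedDataset, simulate_dataset
from .types import ASEventTable, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "analyse_dataset", "build_snp_table"]


@dataclass
class PipelineResult:
    dataset: SimulatedDataset | None
    events_filtered: ASEventTable
    genotypes_filtered: GenotypeMatrix
    pairs: pd.DataFrame
    calls: pd.DataFrame
    best_per_event: pd.DataFrame
    sqtl_pruned: list[str]
    nonsqtl_pruned: list[str]
    matched_controls: list[str]
    sqtl_table: pd.DataFrame
    control_table: pd.DataFrame
    enrichment_functional: list
    enrichment_intervals: list
    enrichment_gwas: list
    candidates: list
    counts: dict[str, int] = field(default_factory=dict)


def build_snp_table(
    genotypes: GenotypeMatrix,
    snp_ids: list[str],
    calls: pd.DataFrame,
    events: ASEventTable,
    annotations,
) -> pd.DataFrame:
    """Per-SNP table (chrom, pos, maf, functional_class, best_as_type)
    used by the enrichment comparisons."""
    table = genotypes.snps.loc[snp_ids, ["chrom", "pos", "maf"]].copy()
    table["functional_class"] = enrichment.classify_functional(annotations, snp_ids)
    best_event = calls["best_event_id"].reindex(snp_ids)
    as_type = events.events["as_type"]
    table["best_as_type"] = [
        as_type.get(ev, "") if isinstance(ev, str) else "" for ev in best_event
    ]
    return table


def analyse_dataset(
    dataset: SimulatedDataset,
    window_bp: int = 100_000,
    alpha: float = 0.05,
    seed: int = 0,
    tf_min_records: int = 0,
    exclude_mhc: bool = False,
) -> PipelineResult:
    """Run every analysis stage on an already-simulated (or loaded) dataset.

    ``tf_min_records`` defaults to 0 here because synthetic TF tracks carry
    honest (small) record counts; pass 50_000 to apply the ENCODE-scale
    inclusion rule to real tracks.
    """
    events_f, audit = filtering.filter_as_events(dataset.events)
    geno_f = filtering.filter_snps(dataset.genotypes, events_f, window_bp=window_bp)
    counts = {
        "n_events_input": dataset.events.n_events,
        "n_events_retained": events_f.n_events,
        "n_events_failed_quality": int((audit["status"] == "failed_quality").sum()),
        "n_events_degenerate": int((audit["status"] == "degenerate").sum()),
        "n_snps_input": dataset.genotypes.n_snps,
        "n_snps_tested_universe": geno_f.n_snps,
    }
    logger.info("event QC: %s", counts)

    pairs = mapping.map_cis_pairs(geno_f, events_f, dataset.covariates, window_bp=window_bp)
    calls = mapping.call_sqtl_snps(pairs, geno_f, events_f, window_bp=window_bp, alpha=alpha)
    best = mapping.best_sqtl_per_event(pairs, calls)
    counts["n_pairs_tested"] = len(pairs)
    counts["n_sqtl_snps"] = int(calls["is_sqtl"].sum())
    counts["n_best_per_event"] = len(best)

    # Pruned sQTL set: best SNP per event, position-sorted, LD-pruned.
    best_snps = sorted(
        set(best["snp_id"]), key=lambda s: (geno_f.snps.loc[s, "chrom"], geno_f.snps.loc[s, "pos"], s)
    )
    sqtl_pruned = ldsets.ld_prune(geno_f, best_snps)
    universe = ldsets.build_nonsqtl_universe(calls)
    universe_sorted = sorted(
        universe, key=lambda s: (geno_f.snps.loc[s, "chrom"], geno_f.snps.loc[s, "pos"], s)
    )
    nonsqtl_pruned = ldsets.ld_prune(geno_f, universe_sorted)
    nonsqtl_meta = geno_f.snps.loc[nonsqtl_pruned]
    matchable, unmatchable = ldsets.drop_unmatchable(
        geno_f.snps.loc[sqtl_pruned], nonsqtl_meta
    )
    if unmatchable:
        logger.warning(
            "%d sQTL SNP(s) in MAF bins with no control candidate dropped "
            "from the comparison sets: %s",
            len(unmatchable),
            unmatchable,
        )
        sqtl_pruned = matchable
    sqtl_meta = geno_f.snps.loc[sqtl_pruned]
    matched = ldsets.match_maf(sqtl_meta, nonsqtl_meta, seed=seed)
    counts["n_sqtl_pruned"] = len(sqtl_pruned)
    counts["n_nonsqtl_universe"] = len(universe)
    counts["n_nonsqtl_pruned"] = len(nonsqtl_pruned)
    counts["n_matched_controls"] = len(matched)

    sqtl_table = build_snp_table(geno_f, sqtl_pruned, calls, events_f, dataset.annotations)
    control_table = build_snp_table(geno_f, matched, calls, events_f, dataset.annotations)

    enr_func, enr_int, enr_gwas = [], [], []
    if len(sqtl_table) and len(control_table):
        enr_func = enrichment.enrich_functional(
            sqtl_table["functional_class"], control_table["functional_class"]
        )
        enr_int = enrichment.enrich_intervals(
            sqtl_table, control_table, dataset.annotations, tf_min_records=tf_min_records
        )
        if len(dataset.gwas.loci):
            enr_gwas.append(
                enrichment.enrich_gwas(
                    sqtl_table,
                    control_table,
                    dataset.gwas.loci,
                    exclude_mhc=exclude_mhc,
                    subset="all",
                    test_name="gwas_loci",
                )
            )
    else:
        logger.warning("empty sQTL or control set; enrichment analyses skipped")

    candidates = triage.triage_candidates(
        calls, pairs, events_f, dataset.gwas, geno_f
    )
    counts["n_candidates"] = len(candidates)

    return PipelineResult(
        dataset=dataset,
        events_filtered=events_f,
        genotypes_filtered=geno_f,
        pairs=pairs,
        calls=calls,
        best_per_event=best,
        sqtl_pruned=sqtl_pruned,
        nonsqtl_pruned=nonsqtl_pruned,
        matched_controls=matched,
        sqtl_table=sqtl_table,
        control_table=control_table,
        enrichment_functional=enr_func,
        enrichment_intervals=enr_int,
        enrichment_gwas=enr_gwas,
        candidates=candidates,
        counts=counts,
    )


def run_pipeline(config: SimConfig, **kwargs) -> PipelineResult:
    """Simulate a study under ``config`` and analyse it end to end."""
    dataset = simulate_dataset(config)
    return analyse_dataset(dataset, seed=config.seed, **kwargs)
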