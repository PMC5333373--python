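"""QC filters that define the analysis universe.

Two event-level filters, applied in a fixed order:

1. quality filter — drop events whose per-sample quality flag fails in
   strictly more than ``quality_fail_frac`` (default 20%) of samples;
2. degenerate-PSI filter — drop events whose PSI equals 0 or equals 100 in
   strictly more than ``degenerate_frac`` (default 90%) of the samples with
   a non-missing PSI.

SNP-level filter: keep SNPs with MAF >= 1% whose gap distance to the
nearest retained event is strictly below the cis window (100 kb). The gap
is 0 when the SNP lies inside the event span, else the distance to the
nearer span end.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._util import min_gap_to_events
from .types import ASEventTable, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["filter_as_events", "filter_snps"]


def filter_as_events(
    events: ASEventTable,
    quality_fail_frac: float = 0.20,
    degenerate_frac: float = 0.90,
) -> tuple[ASEventTable, pd.DataFrame]:
    """Apply both event QC rules; returns (survivors, audit).

    audit has one row per input event with a ``status`` column in
    {"retained", "failed_quality", "degenerate"}; the quality rule is
    applied first, so an event failing both is recorded as failed_quality.
    """
    if events.n_events == 0:
        raise ValueError("event table is empty")
    ok = events.quality_ok.to_numpy()
    psi = events.psi.to_numpy()
    n_samples = ok.shape[1]

    fail_frac = 1.0 - ok.sum(axis=1) / n_samples
    failed_quality = fail_frac > quality_fail_frac

    with np.errstate(invalid="ignore"):
        extreme = (psi == 0.0) | (psi == 100.0)
    n_obs = np.sum(~np.isnan(psi), axis=1)
    degen_frac = np.divide(
        extreme.sum(axis=1), n_obs, out=np.zeros(len(psi)), where=n_obs > 0
    )
    degenerate = ~failed_quality & (degen_frac > degenerate_frac)

    status = np.where(
        failed_quality, "failed_quality", np.where(degenerate, "degenerate", "retained")
    )
    audit = pd.DataFrame({"status": status}, index=events.events.index)
    keep = events.events.index[status == "retained"]
    if len(keep) == 0:
        logger.warning("all %d AS events removed by QC filters", events.n_events)
    return events.subset_events(keep), audit


def filter_snps(
    genotypes: GenotypeMatrix,
    events: ASEventTable,
    maf_min: float = 0.01,
    window_bp: int = 100_000,
    window_inclusive: bool = False,
) -> GenotypeMatrix:
    """Keep SNPs with MAF >= maf_min that lie within the cis window of at
    least one retained event (strict gap < window_bp by default)."""
    snps = genotypes.snps
    keep = np.ones(len(snps), dtype=bool)
    keep &= (snps["maf"] >= maf_min).to_numpy()

    dist = np.full(len(snps), np.iinfo(np.int64).max)
    for chrom, ev in events.events.groupby("chrom", sort=False):
        on_chrom = (snps["chrom"] == chrom).to_numpy()
        if not on_chrom.any():
            continue
        spans = ev[["span_start", "span_end"]].to_numpy(dtype=np.int64)
        dist[on_chrom] = min_gap_to_events(snps.loc[on_chrom, "pos"].to_numpy(), spans)
    keep &= (dist <= window_bp) if window_inclusive else (dist < window_bp)
    return genotypes.subset_snps(snps.index[keep])
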