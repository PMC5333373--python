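"""Credible-set triage of sQTL SNPs inside GWAS risk loci.

A candidate record nominates an sQTL SNP (and the gene whose splicing it
best explains) for a risk locus when the SNP is simultaneously:

1. in LD with the locus index SNP at r^2 strictly above 0.8,
2. itself genome-wide significant in the GWAS (p strictly below 5e-8), and
3. a member of the locus credible set.

When a declared index SNP is missing from the LD reference panel, the most
significantly associated locus SNP that is present substitutes for it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ldsets import UndefinedLDError, compute_r2
from .types import ASEventTable, GenotypeMatrix, GWASPanel, SpliceMapError

logger = logging.getLogger(__name__)

__all__ = ["CandidateRecord", "resolve_index", "triage_candidates", "report"]


@dataclass
class CandidateRecord:
    locus_id: str
    index_snp: str
    sqtl_snp: str
    r2_to_index: float
    gwas_p: float
    event_id: str
    gene: str
    as_type: str
    p_double: float


def resolve_index(
    locus: pd.Series, gwas: GWASPanel, ld_ref: GenotypeMatrix
) -> str | None:
    """Index SNP for a locus, substituting when absent from the LD panel.

    Returns the declared index SNP if the LD reference covers it; otherwise
    the smallest-GWAS-p SNP inside the locus interval that the reference
    covers (ties: earlier position, then ID). None (with a warning) when no
    locus SNP is present in the reference.
    """
    declared = locus.get("index_snp", "")
    known = set(ld_ref.snps.index)
    if isinstance(declared, str) and declared and declared in known:
        return declared
    summary = gwas.summary
    inside = summary[
        (summary["chrom"].astype(str) == str(locus["chrom"]))
        & (summary["pos"] >= locus["start"])
        & (summary["pos"] <= locus["end"])
        & (summary["snp"].isin(known))
    ]
    if inside.empty:
        logger.warning("locus %s: no summary-stat SNP in the LD reference; skipped", locus.get("locus_id"))
        return None
    best = inside.sort_values(["p", "pos", "snp"], kind="stable").iloc[0]
    return str(best["snp"])


def triage_candidates(
    calls: pd.DataFrame,
    pairs: pd.DataFrame,
    events: ASEventTable,
    gwas: GWASPanel,
    ld_ref: GenotypeMatrix,
    r2_min: float = 0.8,
    p_gwas: float = 5e-8,
) -> list[CandidateRecord]:
    """All sQTL SNPs satisfying the three criteria, one record per
    (locus, SNP) with the SNP's best-associated AS event."""
    sqtl_ids = set(calls.index[calls["is_sqtl"]])
    gwas_p_by_snp = gwas.summary.set_index("snp")["p"]
    records: list[CandidateRecord] = []
    for _, locus in gwas.loci.iterrows():
        locus_id = str(locus["locus_id"])
        credible = gwas.credible_set(locus_id)
        if not credible:
            continue
        index_snp = resolve_index(locus, gwas, ld_ref)
        if index_snp is None:
            continue
        for snp in sorted(credible & sqtl_ids):
            if snp not in gwas_p_by_snp.index:
                continue
            snp_p = float(gwas_p_by_snp.loc[snp])
            if not snp_p < p_gwas:
                continue
            if snp not in ld_ref.snps.index:
                continue
            try:
                r2 = compute_r2(ld_ref, index_snp, snp)
            except UndefinedLDError:
                continue
            if not r2 > r2_min:
                continue
            best_event = calls.loc[snp, "best_event_id"]
            ev = events.events.loc[best_event]
            records.append(
                CandidateRecord(
                    locus_id=locus_id,
                    index_snp=index_snp,
                    sqtl_snp=snp,
                    r2_to_index=float(r2),
                    gwas_p=snp_p,
                    event_id=str(best_event),
                    gene=str(ev["gene"]),
                    as_type=str(ev["as_type"]),
                    p_double=float(calls.loc[snp, "p_double"]),
                )
            )
    records.sort(key=lambda r: (r.p_double, r.locus_id, r.sqtl_snp))
    return records


_REPORT_COLUMNS = [
    "locus_id",
    "index_snp",
    "sqtl_snp",
    "r2_to_index",
    "gwas_p",
    "event_id",
    "gene",
    "as_type",
    "p_double",
]


def records_frame(records: list[CandidateRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=_REPORT_COLUMNS)


def report(
    records: list[CandidateRecord],
    events: ASEventTable,
    genotypes: GenotypeMatrix,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Write the per-locus candidate table and a genotype-stratified PSI
    summary (mean/median/IQR of the candidate event's PSI per dosage
    group) for plotting; returns the summary. Output is deterministic."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec_df = records_frame(records)
    rec_df.to_csv(out / "candidates.tsv", sep="\t", index=False)

    rows = []
    for rec in records:
        if rec.event_id not in events.events.index or rec.sqtl_snp not in genotypes.snps.index:
            raise SpliceMapError(f"unknown record reference {rec.event_id}/{rec.sqtl_snp}")
        psi = events.psi.loc[rec.event_id]
        dose = genotypes.dosage.loc[rec.sqtl_snp].round()
        for g in (0.0, 1.0, 2.0):
            vals = psi[(dose == g) & psi.notna()]
            if len(vals) == 0:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append(
                {
                    "locus_id": rec.locus_id,
                    "sqtl_snp": rec.sqtl_snp,
                    "event_id": rec.event_id,
                    "genotype": int(g),
                    "n": int(len(vals)),
                    "mean_psi": float(vals.mean()),
                    "median_psi": float(med),
                    "iqr_low": float(q1),
                    "iqr_high": float(q3),
                }
            )
    summary = pd.DataFrame(
        rows,
        columns=[
            "locus_id",
            "sqtl_snp",
            "event_id",
            "genotype",
            "n",
            "mean_psi",
            "median_psi",
            "iqr_low",
            "iqr_high",
        ],
    )
    summary.to_csv(out / "psi_by_genotype.tsv", sep="\t", index=False)
    return summary
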