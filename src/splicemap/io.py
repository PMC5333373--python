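"""Readers and writers for every table format the pipeline touches.

Conventions
-----------
* Genotypes TSV: one row per SNP — snp_id, chrom, pos (1-based), ref, alt,
  then per-sample dosages in {0, 1, 2} ("NA" for missing). VCF is accepted
  as an alternative genotype source (GT converted to alt-allele dosage;
  multi-allelic records rejected).
* PSI TSV (vast-tools combine style): event_id, gene, as_type, chrom,
  span_start, span_end, then per-sample "PSI@Q" tokens where Q is a
  pass/fail quality token (OK / LOW); "NA@LOW" marks a missing value.
* Covariates TSV: sample_id plus covariate columns.
* Annotation tracks: BED, 0-based half-open (the only place 0-based
  coordinates appear).
* GWAS: summary TSV (snp, chrom, pos, p), loci TSV
  (locus_id, chrom, start, end, index_snp) and credible-set TSV
  (locus_id, snp).
"""

from __future__ import annotations

import math
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SimulatedDataset
from .types import (
    ASEventTable,
    AnnotationSet,
    CovariateTable,
    GenotypeMatrix,
    GWASPanel,
    SpliceMapError,
    Track,
)

__all__ = [
    "read_genotypes",
    "read_genotypes_vcf",
    "read_psi",
    "read_covariates",
    "read_dataset",
    "align_samples",
    "write_genotypes",
    "write_psi",
    "write_covariates",
    "write_tracks",
    "read_track_bed",
    "write_gwas",
    "read_gwas",
    "write_dataset",
]

_QUALITY_PASS = "OK"
_QUALITY_FAIL = "LOW"


class ParseError(SpliceMapError):
    """Malformed input file; message carries file/row/column location."""


# ---------------------------------------------------------------- genotypes


def write_genotypes(geno: GenotypeMatrix, path: str | os.PathLike) -> None:
    df = geno.snps[["chrom", "pos", "ref", "alt"]].copy()
    dosage = geno.dosage.round().astype("Int64")
    out = pd.concat([df, dosage], axis=1)
    out.to_csv(path, sep="\t", index_label="snp_id", na_rep="NA")


def read_genotypes(path: str | os.PathLike) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"])
    required = ["snp_id", "chrom", "pos", "ref", "alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing genotype columns {missing}")
    df = df.set_index("snp_id")
    snps = df[["chrom", "pos", "ref", "alt"]].copy()
    snps["pos"] = snps["pos"].astype(np.int64)
    dosage = df.drop(columns=["chrom", "pos", "ref", "alt"]).astype(float)
    bad = dosage.stack(future_stack=True).dropna()
    if not bad.isin([0.0, 1.0, 2.0]).all():
        culprit = bad[~bad.isin([0.0, 1.0, 2.0])].index[0]
        raise ParseError(f"{path}: dosage not in {{0,1,2}} at SNP {culprit[0]!r}, sample {culprit[1]!r}")
    geno = GenotypeMatrix(snps, dosage)
    geno.recompute_maf()
    return geno


def read_genotypes_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Genotypes from a (possibly uncompressed) VCF; GT field -> dosage."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosages = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ParseError(f"{path}: multi-allelic record at {var.CHROM}:{var.POS} not supported")
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        rows.append((snp_id, var.CHROM, var.POS, var.REF, var.ALT[0]))
        gt = var.gt_types.astype(float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dose = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        dosages.append(dose)
    snps = pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "ref", "alt"]
    ).set_index("snp_id")
    snps["pos"] = snps["pos"].astype(np.int64)
    dosage = pd.DataFrame(np.asarray(dosages), index=snps.index, columns=samples)
    geno = GenotypeMatrix(snps, dosage)
    geno.recompute_maf()
    return geno


# ---------------------------------------------------------------------- psi


def write_psi(events: ASEventTable, path: str | os.PathLike) -> None:
    meta = events.events[["gene", "as_type", "chrom", "span_start", "span_end"]]
    psi = events.psi.to_numpy()
    ok = events.quality_ok.to_numpy()
    tokens = np.empty(psi.shape, dtype=object)
    for i in range(psi.shape[0]):
        for j in range(psi.shape[1]):
            val = "NA" if math.isnan(psi[i, j]) else format(psi[i, j], ".4f")
            tokens[i, j] = f"{val}@{_QUALITY_PASS if ok[i, j] else _QUALITY_FAIL}"
    tok = pd.DataFrame(tokens, index=events.events.index, columns=events.psi.columns)
    pd.concat([meta, tok], axis=1).to_csv(path, sep="\t", index_label="event_id")


def read_psi(path: str | os.PathLike) -> ASEventTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["event_id", "gene", "as_type", "chrom", "span_start", "span_end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing PSI columns {missing}")
    df = df.set_index("event_id")
    meta = df[["gene", "as_type", "chrom", "span_start", "span_end"]].copy()
    meta["span_start"] = meta["span_start"].astype(np.int64)
    meta["span_end"] = meta["span_end"].astype(np.int64)
    token_cols = [c for c in df.columns if c not in meta.columns]
    psi = np.full((len(df), len(token_cols)), np.nan)
    ok = np.zeros((len(df), len(token_cols)), dtype=bool)
    for j, col in enumerate(token_cols):
        for i, (event_id, token) in enumerate(zip(df.index, df[col].astype(str))):
            parts = token.split("@")
            if len(parts) != 2 or parts[1] not in (_QUALITY_PASS, _QUALITY_FAIL):
                raise ParseError(
                    f"{path}: malformed PSI token {token!r} at event {event_id!r}, sample {col!r}"
                )
            val_str, qual = parts
            if val_str != "NA":
                try:
                    val = float(val_str)
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric PSI {val_str!r} at event {event_id!r}, sample {col!r}"
                    ) from None
                if not 0.0 <= val <= 100.0:
                    raise ParseError(
                        f"{path}: PSI {val_str} outside [0, 100] at event {event_id!r}, sample {col!r}"
                    )
                psi[i, j] = val
            ok[i, j] = qual == _QUALITY_PASS and val_str != "NA"
    return ASEventTable(
        meta,
        pd.DataFrame(psi, index=meta.index, columns=token_cols),
        pd.DataFrame(ok, index=meta.index, columns=token_cols),
    )


# --------------------------------------------------------------- covariates


def write_covariates(cov: CovariateTable, path: str | os.PathLike) -> None:
    cov.df.to_csv(path, sep="\t", index_label="sample_id")


def read_covariates(path: str | os.PathLike) -> CovariateTable:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing sample_id column")
    return CovariateTable(df.set_index("sample_id"))


# ---------------------------------------------------------------- alignment


def align_samples(
    geno: GenotypeMatrix, events: ASEventTable, cov: CovariateTable
) -> tuple[GenotypeMatrix, ASEventTable, CovariateTable]:
    """Restrict the three tables to their common samples, in one canonical
    (sorted) order, and recompute MAF on that analysis sample set."""
    common = sorted(set(geno.samples) & set(events.samples) & set(cov.samples))
    if not common:
        raise SpliceMapError("no overlapping samples between genotypes, PSI and covariates")
    return geno.subset_samples(common), events.subset_samples(common), cov.subset_samples(common)


def read_dataset(
    genotypes_path: str | os.PathLike,
    psi_path: str | os.PathLike,
    covariates_path: str | os.PathLike,
    genotype_format: str = "tsv",
) -> tuple[GenotypeMatrix, ASEventTable, CovariateTable]:
    """Read and sample-align the three analysis tables."""
    if genotype_format == "tsv":
        geno = read_genotypes(genotypes_path)
    elif genotype_format == "vcf":
        geno = read_genotypes_vcf(genotypes_path)
    else:
        raise SpliceMapError(f"unknown genotype format {genotype_format!r}")
    return align_samples(geno, read_psi(psi_path), read_covariates(covariates_path))


# -------------------------------------------------------------- annotations


def write_tracks(annotations: AnnotationSet, out_dir: str | os.PathLike) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotations.functional.to_csv(out / "functional.tsv", sep="\t", index=False)
    for track in annotations.tracks.values():
        track.intervals.to_csv(
            out / f"{track.family}__{track.name}.bed", sep="\t", index=False, header=False
        )


def read_track_bed(path: str | os.PathLike, name: str, family: str) -> Track:
    """One BED track; n_records is the file's record (line) count."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {ln}: BED needs >=3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}: line {ln}: non-integer BED coordinates") from None
            if start < 0 or end < start:
                raise ParseError(f"{path}: line {ln}: invalid BED interval [{start}, {end})")
            rows.append((parts[0], start, end))
    iv = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return Track(name=name, family=family, intervals=iv, n_records=len(iv))


def read_tracks(tracks_dir: str | os.PathLike) -> AnnotationSet:
    out_dir = Path(tracks_dir)
    functional_path = out_dir / "functional.tsv"
    functional = (
        pd.read_csv(functional_path, sep="\t")
        if functional_path.exists()
        else pd.DataFrame(columns=["snp_id", "label"])
    )
    tracks = {}
    for path in sorted(out_dir.glob("*.bed")):
        family, _, name = path.stem.partition("__")
        tracks[name] = read_track_bed(path, name=name, family=family)
    return AnnotationSet(functional, tracks)


# --------------------------------------------------------------------- gwas


def write_gwas(gwas: GWASPanel, out_dir: str | os.PathLike) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gwas.summary.to_csv(out / "gwas_summary.tsv", sep="\t", index=False)
    gwas.loci.to_csv(out / "gwas_loci.tsv", sep="\t", index=False)
    gwas.credible.to_csv(out / "credible_sets.tsv", sep="\t", index=False)


def read_gwas(out_dir: str | os.PathLike) -> GWASPanel:
    out = Path(out_dir)
    summary = pd.read_csv(out / "gwas_summary.tsv", sep="\t", dtype={"chrom": str})
    loci = pd.read_csv(
        out / "gwas_loci.tsv", sep="\t", dtype={"chrom": str}, keep_default_na=False
    )
    credible = pd.read_csv(out / "credible_sets.tsv", sep="\t")
    return GWASPanel(summary, loci, credible)


# ------------------------------------------------------------ full dataset


def write_dataset(dataset: SimulatedDataset, out_dir: str | os.PathLike) -> None:
    """Write a complete simulated study in all the on-disk formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genotypes(dataset.genotypes, out / "genotypes.tsv")
    write_psi(dataset.events, out / "psi.tsv")
    write_covariates(dataset.covariates, out / "covariates.tsv")
    write_tracks(dataset.annotations, out / "annotations")
    write_gwas(dataset.gwas, out / "gwas")
    pd.DataFrame(
        {
            "causal_snp_id": dataset.truth.causal_snp_ids,
            "causal_event_id": dataset.truth.causal_event_ids,
            "planted_beta": dataset.truth.planted_betas,
        }
    ).to_csv(out / "truth.tsv", sep="\t", index=False)
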