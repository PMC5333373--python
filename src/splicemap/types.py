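"""Core in-memory containers shared by every pipeline stage.

All tables are thin wrappers around pandas DataFrames so that the standard
tooling (indexing, joins, I/O) stays available, while the wrappers pin down
the invariants each stage relies on: dosages in {0, 1, 2} (NaN for missing),
PSI in [0, 100] (NaN for missing), 1-based inclusive genomic coordinates in
memory, 0-based half-open only at BED boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpliceMapError",
    "InvalidConfigError",
    "GenotypeMatrix",
    "ASEventTable",
    "CovariateTable",
    "TruthTable",
    "Track",
    "AnnotationSet",
    "GWASPanel",
    "AS_TYPES",
]

AS_TYPES = ("AltEX", "AltSS5", "AltSS3", "IR")


class SpliceMapError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(SpliceMapError):
    """Raised for invalid simulation or pipeline configuration."""


def _minor_allele_freq(dosage: pd.DataFrame) -> pd.Series:
    """Per-SNP minor allele frequency from non-missing dosages."""
    p_alt = dosage.mean(axis=1, skipna=True) / 2.0
    return np.minimum(p_alt, 1.0 - p_alt)


@dataclass
class GenotypeMatrix:
    """SNP panel: metadata plus a samples-wide dosage table.

    Attributes
    ----------
    snps : DataFrame indexed by snp_id with columns chrom, pos (1-based),
        ref, alt, maf.
    dosage : DataFrame indexed by snp_id, one column per sample; values in
        {0, 1, 2} with NaN for missing calls.
    """

    snps: pd.DataFrame
    dosage: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.snps.index.equals(self.dosage.index):
            raise SpliceMapError("snps and dosage must share the same SNP index")
        if self.snps.index.has_duplicates:
            raise SpliceMapError("duplicated SNP ids")
        if self.dosage.columns.has_duplicates:
            raise SpliceMapError("duplicated sample ids")

    @property
    def samples(self) -> list[str]:
        return list(self.dosage.columns)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def recompute_maf(self) -> None:
        """Refresh the maf column from the current sample set."""
        self.snps["maf"] = _minor_allele_freq(self.dosage)

    def subset_samples(self, samples: list[str]) -> "GenotypeMatrix":
        out = GenotypeMatrix(self.snps.copy(), self.dosage.loc[:, samples].copy())
        out.recompute_maf()
        return out

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.snps.loc[snp_ids].copy(), self.dosage.loc[snp_ids].copy())


@dataclass
class ASEventTable:
    """Alternative-splicing events with per-sample PSI and quality flags.

    Attributes
    ----------
    events : DataFrame indexed by event_id with columns gene, as_type,
        chrom, span_start, span_end (1-based inclusive).
    psi : DataFrame indexed by event_id, per-sample percent-spliced-in in
        [0, 100], NaN for missing.
    quality_ok : boolean DataFrame, same shape as psi; True where the
        event passed the per-sample read-coverage quality check.
    """

    events: pd.DataFrame
    psi: pd.DataFrame
    quality_ok: pd.DataFrame

    def __post_init__(self) -> None:
        if not (self.events.index.equals(self.psi.index) and self.psi.index.equals(self.quality_ok.index)):
            raise SpliceMapError("events, psi and quality_ok must share the same event index")
        if self.events.index.has_duplicates:
            raise SpliceMapError("duplicated event ids")
        bad_span = self.events["span_start"] > self.events["span_end"]
        if bad_span.any():
            raise SpliceMapError(f"span_start > span_end for events {list(self.events.index[bad_span])}")
        vals = self.psi.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0.0 or np.nanmax(vals, initial=100.0) > 100.0:
                raise SpliceMapError("PSI values must lie in [0, 100]")

    @property
    def samples(self) -> list[str]:
        return list(self.psi.columns)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def subset_samples(self, samples: list[str]) -> "ASEventTable":
        return ASEventTable(
            self.events.copy(), self.psi.loc[:, samples].copy(), self.quality_ok.loc[:, samples].copy()
        )

    def subset_events(self, event_ids) -> "ASEventTable":
        return ASEventTable(
            self.events.loc[event_ids].copy(),
            self.psi.loc[event_ids].copy(),
            self.quality_ok.loc[event_ids].copy(),
        )


@dataclass
class CovariateTable:
    """Per-sample covariates; numeric columns used as-is, object columns
    expanded to drop-first indicator columns in the design matrix."""

    df: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            raise SpliceMapError("duplicated sample ids in covariates")

    @property
    def samples(self) -> list[str]:
        return list(self.df.index)

    def subset_samples(self, samples: list[str]) -> "CovariateTable":
        return CovariateTable(self.df.loc[samples].copy())

    def design_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Numeric design matrix (no intercept column) and column names.

        Categorical (object/category dtype) covariates are encoded as
        drop-first indicators; numeric covariates enter untransformed.
        """
        cols: list[pd.Series] = []
        names: list[str] = []
        for name in self.df.columns:
            col = self.df[name]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                levels = sorted(pd.unique(col.astype(str)))
                for level in levels[1:]:
                    cols.append((col.astype(str) == level).astype(float))
                    names.append(f"{name}[{level}]")
            else:
                cols.append(col.astype(float))
                names.append(name)
        if not cols:
            return np.empty((len(self.df), 0)), []
        mat = np.column_stack([c.to_numpy() for c in cols])
        return mat, names


@dataclass
class TruthTable:
    """Ground truth of planted cis effects, for recovery checks."""

    causal_snp_ids: list[str]
    causal_event_ids: list[str]
    planted_betas: list[float]
    planted_locus_overlaps: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.causal_snp_ids)
        if not (len(self.causal_event_ids) == n and len(self.planted_betas) == n):
            raise SpliceMapError("truth table columns must have equal length")


@dataclass
class Track:
    """One labelled genomic interval track (BED semantics: 0-based half-open).

    n_records is the record count of the source annotation file; for ENCODE
    transcription-factor tracks this drives the >=50,000-record inclusion
    filter, so it is carried explicitly rather than recomputed from a
    possibly down-sampled interval table.
    """

    name: str
    family: str  # "element" or "tf"
    intervals: pd.DataFrame  # columns chrom, start, end
    n_records: int = -1

    def __post_init__(self) -> None:
        if self.family not in ("element", "tf"):
            raise SpliceMapError(f"unknown track family {self.family!r}")
        if self.n_records < 0:
            self.n_records = len(self.intervals)


@dataclass
class AnnotationSet:
    """Functional class labels per SNP plus regulatory interval tracks."""

    functional: pd.DataFrame  # long form: columns snp_id, label
    tracks: dict[str, Track]

    def labels_for(self) -> dict[str, set[str]]:
        """snp_id -> set of functional labels (SNPs may be absent: no label)."""
        out: dict[str, set[str]] = {}
        for snp_id, label in self.functional.itertuples(index=False):
            out.setdefault(snp_id, set()).add(label)
        return out


@dataclass
class GWASPanel:
    """GWAS summary statistics with risk loci and per-locus credible sets."""

    summary: pd.DataFrame  # columns snp, chrom, pos, p
    loci: pd.DataFrame  # columns locus_id, chrom, start, end, index_snp
    credible: pd.DataFrame  # columns locus_id, snp

    def __post_init__(self) -> None:
        declared = set(self.loci["index_snp"].dropna()) - {""}
        known = set(self.summary["snp"])
        missing = declared - known
        if missing:
            raise SpliceMapError(f"index SNPs absent from summary stats: {sorted(missing)}")

    def credible_set(self, locus_id: str) -> set[str]:
        sel = self.credible["locus_id"] == locus_id
        return set(self.credible.loc[sel, "snp"])
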