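"""cis sQTL mapping: additive linear model plus the two-layer correction.

For every SNP-event pair whose gap distance is strictly below the cis
window (100 kb), percent-spliced-in is regressed on allele dosage with an
intercept and the covariate design. Two-sided p-values come from the t
distribution with n - k - 2 residual degrees of freedom (intercept +
genotype + k covariate columns).

Multiple testing is the "double correction": Benjamini-Hochberg across the
full pair list, then, per SNP, the smallest adjusted p is Bonferroni-scaled
by the number of retained AS events inside that SNP's window (counted from
the event table, not from the tested pairs), capped at 1. A SNP is called
an sQTL when this double-corrected p falls below 0.05.

Missing data: dosages are mean-imputed per SNP before regression; samples
with missing PSI are dropped pairwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import gap_distance
from .types import ASEventTable, CovariateTable, GenotypeMatrix, SpliceMapError

logger = logging.getLogger(__name__)

__all__ = [
    "fit_additive_model",
    "map_cis_pairs",
    "benjamini_hochberg",
    "call_sqtl_snps",
    "best_sqtl_per_event",
    "count_local_events",
    "FitResult",
]

MIN_SAMPLES = 10


class ZeroVarianceError(SpliceMapError):
    """Dosage has no variance on the analysed samples."""


class InsufficientDataError(SpliceMapError):
    """Fewer than MIN_SAMPLES samples with both PSI and dosage."""


@dataclass
class FitResult:
    beta: float
    se: float
    t_stat: float
    p: float
    n_used: int


def _prune_collinear(design: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Greedily drop columns that do not increase the rank; returns the
    pruned matrix and the kept column indices."""
    kept: list[int] = []
    for j in range(design.shape[1]):
        cand = design[:, kept + [j]]
        if np.linalg.matrix_rank(cand) > len(kept):
            kept.append(j)
    return design[:, kept], kept


def mean_impute(dosage: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-SNP mean (Matrix eQTL convention)."""
    dosage = np.asarray(dosage, dtype=float)
    if dosage.ndim == 1:
        dosage = dosage[None, :]
        squeeze = True
    else:
        squeeze = False
    out = dosage.copy()
    means = np.nanmean(out, axis=1)
    idx = np.where(np.isnan(out))
    out[idx] = means[idx[0]]
    return out[0] if squeeze else out


def fit_additive_model(
    psi: np.ndarray,
    dosage: np.ndarray,
    covariates: np.ndarray | None = None,
) -> FitResult:
    """OLS of PSI on dosage with intercept and covariates, for one pair.

    Samples with missing PSI are dropped; missing dosages are mean-imputed
    across all samples first. Constant PSI yields beta = 0, p = 1.
    """
    psi = np.asarray(psi, dtype=float)
    g = mean_impute(dosage)
    if covariates is None:
        covariates = np.empty((len(psi), 0))
    covariates = np.asarray(covariates, dtype=float)

    use = ~np.isnan(psi) & ~np.isnan(g)
    n = int(use.sum())
    if n < MIN_SAMPLES:
        raise InsufficientDataError(f"only {n} usable samples (need >= {MIN_SAMPLES})")
    y, gv, C = psi[use], g[use], covariates[use]

    if np.ptp(gv) == 0.0:
        raise ZeroVarianceError("dosage constant on analysed samples")

    C_pruned, kept = _prune_collinear(np.column_stack([np.ones(n), C]))
    if len(kept) < C.shape[1] + 1:
        logger.warning("pruned %d rank-deficient covariate column(s)", C.shape[1] + 1 - len(kept))
    k = C_pruned.shape[1] - 1  # covariate columns excluding intercept
    X = np.column_stack([C_pruned[:, :1], gv, C_pruned[:, 1:]])
    df = n - k - 2
    if df <= 0:
        raise InsufficientDataError(f"no residual degrees of freedom (n={n}, k={k})")

    if np.ptp(y) == 0.0:
        return FitResult(beta=0.0, se=np.nan, t_stat=0.0, p=1.0, n_used=n)

    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta = float(coef[1])
    if se == 0.0:
        return FitResult(
            beta=beta, se=0.0, t_stat=np.inf * np.sign(beta), p=np.nextafter(0, 1), n_used=n
        )
    t = beta / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return FitResult(beta=beta, se=se, t_stat=t, p=max(p, np.nextafter(0, 1)), n_used=n)


def _candidate_snps(
    snp_pos: np.ndarray, span_start: int, span_end: int, window_bp: int, inclusive: bool
) -> np.ndarray:
    """Indices (into the position-sorted SNP array) within the cis window."""
    pad = window_bp if inclusive else window_bp - 1
    lo = np.searchsorted(snp_pos, span_start - pad, side="left")
    hi = np.searchsorted(snp_pos, span_end + pad, side="right")
    return np.arange(lo, hi)


def map_cis_pairs(
    genotypes: GenotypeMatrix,
    events: ASEventTable,
    covariates: CovariateTable,
    window_bp: int = 100_000,
    window_inclusive: bool = False,
) -> pd.DataFrame:
    """Fit the additive model for every cis pair; BH-adjust jointly.

    Returns a DataFrame with columns snp_id, event_id, beta, se, t, p,
    p_bh, distance_bp. Pairs whose dosage is constant on the analysed
    samples, or with too few usable samples, are skipped (logged).

    The vectorised path residualises PSI and dosage on the covariate
    design per event (Frisch-Waugh), which is algebraically identical to
    the full OLS fit of :func:`fit_additive_model`.
    """
    if list(genotypes.samples) != list(events.samples) or list(events.samples) != list(
        covariates.samples
    ):
        raise SpliceMapError("inputs must be sample-aligned (see io.align_samples)")

    cov_design, _ = covariates.design_matrix()
    dosage_all = mean_impute(genotypes.dosage.to_numpy())
    snp_ids = np.asarray(genotypes.snps.index)
    rows: list[tuple] = []
    n_skipped = 0

    for chrom, ev_chrom in events.events.groupby("chrom", sort=False):
        on_chrom = (genotypes.snps["chrom"] == chrom).to_numpy()
        if not on_chrom.any():
            continue
        chrom_idx = np.where(on_chrom)[0]
        order = np.argsort(genotypes.snps.loc[on_chrom, "pos"].to_numpy(), kind="stable")
        chrom_idx = chrom_idx[order]
        pos_sorted = genotypes.snps["pos"].to_numpy()[chrom_idx]

        for event_id, ev in ev_chrom.iterrows():
            cand = _candidate_snps(
                pos_sorted, ev["span_start"], ev["span_end"], window_bp, window_inclusive
            )
            if len(cand) == 0:
                continue
            sel = chrom_idx[cand]
            dist = gap_distance(pos_sorted[cand], ev["span_start"], ev["span_end"])

            y_full = events.psi.loc[event_id].to_numpy(dtype=float)
            use = ~np.isnan(y_full)
            n = int(use.sum())
            if n < MIN_SAMPLES:
                n_skipped += len(sel)
                continue
            y = y_full[use]
            Z, _ = _prune_collinear(np.column_stack([np.ones(n), cov_design[use]]))
            k = Z.shape[1] - 1
            df = n - k - 2
            if df <= 0:
                n_skipped += len(sel)
                continue
            Q, _ = np.linalg.qr(Z)
            ry = y - Q @ (Q.T @ y)
            G = dosage_all[np.ix_(sel, np.where(use)[0])]
            RG = G - (G @ Q) @ Q.T
            gg = np.einsum("ij,ij->i", RG, RG)
            gy = RG @ ry
            yy = float(ry @ ry)

            ok = gg > 1e-12
            n_skipped += int((~ok).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                beta = np.where(ok, gy / np.where(ok, gg, 1.0), np.nan)
                rss = np.maximum(yy - beta**2 * gg, 0.0)
                sigma2 = rss / df
                se = np.sqrt(sigma2 / np.where(ok, gg, 1.0))
                t = np.where(
                    se > 0,
                    beta / np.where(se > 0, se, 1.0),
                    np.where(beta != 0, np.inf * np.sign(beta), 0.0),
                )
            p = 2.0 * stats.t.sf(np.abs(t), df)
            if yy == 0.0:  # constant PSI: no association signal by definition
                beta, t, p = np.zeros_like(beta), np.zeros_like(t), np.ones_like(p)
                se = np.full_like(se, np.nan)
            p = np.maximum(p, np.nextafter(0, 1))
            for i in np.where(ok)[0]:
                rows.append(
                    (
                        snp_ids[sel[i]],
                        event_id,
                        float(beta[i]),
                        float(se[i]),
                        float(t[i]),
                        float(p[i]),
                        int(dist[i]),
                    )
                )

    if not rows:
        logger.warning("no cis pairs found")
        return pd.DataFrame(
            columns=["snp_id", "event_id", "beta", "se", "t", "p", "p_bh", "distance_bp"]
        )
    if n_skipped:
        logger.info("skipped %d pair(s) (zero dosage variance or too few samples)", n_skipped)
    pairs = pd.DataFrame(
        rows, columns=["snp_id", "event_id", "beta", "se", "t", "p", "distance_bp"]
    )
    pairs["p_bh"] = benjamini_hochberg(pairs["p"].to_numpy())
    return pairs[["snp_id", "event_id", "beta", "se", "t", "p", "p_bh", "distance_bp"]]


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Step-up BH adjustment: adj_i = min_{rank k >= rank(i)} p_(k) * m / k, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def count_local_events(
    genotypes: GenotypeMatrix,
    events: ASEventTable,
    window_bp: int = 100_000,
    window_inclusive: bool = False,
) -> pd.Series:
    """Per-SNP count of retained AS events within the cis window.

    This is the local Bonferroni multiplier; it counts events from the
    filtered event table even where a specific pair was skipped.
    """
    counts = np.zeros(genotypes.n_snps, dtype=np.int64)
    snp_pos_all = genotypes.snps["pos"].to_numpy()
    for chrom, ev_chrom in events.events.groupby("chrom", sort=False):
        on_chrom = (genotypes.snps["chrom"] == chrom).to_numpy()
        if not on_chrom.any():
            continue
        chrom_idx = np.where(on_chrom)[0]
        order = np.argsort(snp_pos_all[chrom_idx], kind="stable")
        chrom_idx = chrom_idx[order]
        pos_sorted = snp_pos_all[chrom_idx]
        for _, ev in ev_chrom.iterrows():
            cand = _candidate_snps(
                pos_sorted, ev["span_start"], ev["span_end"], window_bp, window_inclusive
            )
            counts[chrom_idx[cand]] += 1
    return pd.Series(counts, index=genotypes.snps.index, name="n_local_events")


def call_sqtl_snps(
    pairs: pd.DataFrame,
    genotypes: GenotypeMatrix,
    events: ASEventTable,
    window_bp: int = 100_000,
    alpha: float = 0.05,
    window_inclusive: bool = False,
) -> pd.DataFrame:
    """Per-SNP double-corrected verdicts.

    Returns a DataFrame indexed by snp_id with columns min_p_raw, min_p_bh,
    n_local_events, p_double, is_sqtl, best_event_id.
    """
    if pairs.empty:
        return pd.DataFrame(
            columns=["min_p_raw", "min_p_bh", "n_local_events", "p_double", "is_sqtl", "best_event_id"]
        )
    n_local = count_local_events(genotypes, events, window_bp, window_inclusive)

    # Deterministic best pair per SNP: smallest p, then distance, then event id.
    ordered = pairs.sort_values(
        ["p", "distance_bp", "event_id"], kind="stable"
    ).drop_duplicates("snp_id")
    grouped = pairs.groupby("snp_id")
    calls = pd.DataFrame(
        {
            "min_p_raw": grouped["p"].min(),
            "min_p_bh": grouped["p_bh"].min(),
        }
    )
    calls["n_local_events"] = n_local.reindex(calls.index)
    if (calls["n_local_events"] < 1).any():
        raise SpliceMapError("tested SNP with zero countable local events")
    calls["p_double"] = np.minimum(1.0, calls["min_p_bh"] * calls["n_local_events"])
    calls["is_sqtl"] = calls["p_double"] < alpha
    calls["best_event_id"] = ordered.set_index("snp_id")["event_id"].reindex(calls.index)
    calls.index.name = "snp_id"
    return calls


def best_sqtl_per_event(pairs: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Best sQTL SNP per AS event.

    For each event with at least one sQTL SNP among its pairs, the pair
    with the smallest p; ties broken by smaller distance, then
    lexicographic snp_id. Returns a DataFrame (event_id, snp_id).
    """
    sqtl_ids = set(calls.index[calls["is_sqtl"]])
    cand = pairs[pairs["snp_id"].isin(sqtl_ids)]
    if cand.empty:
        return pd.DataFrame(columns=["event_id", "snp_id"])
    best = (
        cand.sort_values(["p", "distance_bp", "snp_id"], kind="stable")
        .drop_duplicates("event_id")
        .loc[:, ["event_id", "snp_id"]]
        .sort_values("event_id", ignore_index=True)
    )
    return best
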