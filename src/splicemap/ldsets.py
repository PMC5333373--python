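"""LD computation, pruning, control-set construction and locus expansion.

r^2 is the squared Pearson correlation of unphased dosage vectors over
pairwise-complete samples (close to PLINK's composite measure, no phasing
needed). Pruning follows the PLINK indep-pairwise scheme — sliding window
of 50 SNPs advanced by 5, removing one member of every within-window pair
with r^2 > 0.5 — with a deterministic removal rule: the lower-MAF SNP goes
first (MAF tie: the later position).

The non-sQTL control universe keeps SNPs whose smallest uncorrected pair
p-value is strictly above 0.05; MAF matching stratifies both sets into 2%
MAF bins and draws, per bin, a number of controls proportional to the
sQTL bin counts (floor plus largest-remainder top-up), deterministically
under a seed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, GWASPanel, SpliceMapError

logger = logging.getLogger(__name__)

__all__ = [
    "compute_r2",
    "r2_matrix",
    "ld_prune",
    "build_nonsqtl_universe",
    "match_maf",
    "maf_bin_index",
    "expand_locus",
]


class UndefinedLDError(SpliceMapError):
    """r^2 undefined because one SNP has zero dosage variance."""


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    use = ~np.isnan(x) & ~np.isnan(y)
    xv, yv = x[use], y[use]
    if len(xv) < 2 or np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
        raise UndefinedLDError("zero dosage variance over pairwise-complete samples")
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def compute_r2(genotypes: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Squared dosage correlation between two SNPs (pairwise-complete)."""
    x = genotypes.dosage.loc[snp_a].to_numpy(dtype=float)
    y = genotypes.dosage.loc[snp_b].to_numpy(dtype=float)
    return _pairwise_r2(x, y)


def r2_matrix(dosage: np.ndarray) -> np.ndarray:
    """All-pairs r^2 for a (snps x samples) dosage block without missing
    values; rows with zero variance yield NaN against every partner."""
    d = np.asarray(dosage, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(d)
    if np.ndim(r) == 0:  # single SNP
        r = np.array([[1.0]])
    return r * r


def ld_prune(
    genotypes: GenotypeMatrix,
    snp_list: list[str],
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.5,
) -> list[str]:
    """Greedy indep-pairwise pruning of a (chrom, pos)-sorted SNP list.

    Within each sliding window, while any surviving pair has r^2 > r2_max,
    the currently highest-r^2 offending pair loses its lower-MAF member
    (MAF tie: the SNP at the later position). The returned list satisfies
    the postcondition exactly: no surviving within-window pair with
    r^2 > r2_max.
    """
    if not snp_list:
        return []
    meta = genotypes.snps.loc[snp_list]
    sorted_meta = meta.sort_values(["chrom", "pos"], kind="stable")
    if list(sorted_meta.index) != list(snp_list):
        raise SpliceMapError("snp_list must be sorted by (chrom, pos)")

    dosage = genotypes.dosage.loc[snp_list].to_numpy(dtype=float)
    # Missing dosages would make window r^2 sample-dependent; impute to mean.
    means = np.nanmean(dosage, axis=1)
    nan_idx = np.where(np.isnan(dosage))
    dosage[nan_idx] = means[nan_idx[0]]
    maf = meta["maf"].to_numpy()
    pos = meta["pos"].to_numpy()
    m = len(snp_list)
    alive = np.ones(m, dtype=bool)

    starts = range(0, max(1, m - 1), step_snps)
    for start in starts:
        window = np.arange(start, min(start + window_snps, m))
        if len(window) < 2:
            continue
        while True:
            live = window[alive[window]]
            if len(live) < 2:
                break
            r2 = r2_matrix(dosage[live])
            np.fill_diagonal(r2, 0.0)
            r2 = np.nan_to_num(r2)
            if r2.max() <= r2_max:
                break
            a, b = np.unravel_index(np.argmax(r2), r2.shape)
            i, j = live[a], live[b]
            if maf[i] < maf[j] or (maf[i] == maf[j] and pos[i] > pos[j]):
                alive[i] = False
            else:
                alive[j] = False
        if window[-1] >= m - 1:
            break
    return [snp_list[i] for i in np.where(alive)[0]]


def build_nonsqtl_universe(calls: pd.DataFrame, p_floor: float = 0.05) -> list[str]:
    """SNPs whose smallest uncorrected local p is strictly above p_floor."""
    keep = calls["min_p_raw"] > p_floor
    out = list(calls.index[keep])
    if not out:
        logger.warning("non-sQTL universe is empty: every SNP associates at p <= %g", p_floor)
    assert not any(calls.loc[out, "is_sqtl"]), "sQTL leaked into the non-sQTL universe"
    return out


def maf_bin_index(maf: np.ndarray, bin_width: float = 0.02) -> np.ndarray:
    """2% MAF bins [0, 0.02), [0.02, 0.04), ... [0.48, 0.50]."""
    n_bins = int(round(0.5 / bin_width))
    idx = np.floor(np.asarray(maf, dtype=float) / bin_width).astype(int)
    return np.minimum(idx, n_bins - 1)  # maf == 0.5 joins the last bin


def match_maf(
    sqtl_snps: pd.DataFrame,
    control_universe: pd.DataFrame,
    bin_width: float = 0.02,
    seed: int = 0,
) -> list[str]:
    """MAF-matched control subset, proportional-scaling rule.

    Both inputs are DataFrames indexed by snp_id with a ``maf`` column.
    Scaling factor s = min over non-empty sQTL bins of
    (controls in bin / sQTLs in bin); the global budget floor(s * n_sqtl)
    is allocated per bin as floor(s * sQTL count) plus a largest-remainder
    top-up, then sampled without replacement under ``seed``.
    """
    if sqtl_snps.empty:
        return []
    s_bins = maf_bin_index(sqtl_snps["maf"].to_numpy(), bin_width)
    c_bins = maf_bin_index(control_universe["maf"].to_numpy(), bin_width)
    occupied = np.unique(s_bins)
    sqtl_counts = {b: int((s_bins == b).sum()) for b in occupied}
    ctrl_counts = {b: int((c_bins == b).sum()) for b in occupied}
    empty = [b for b in occupied if ctrl_counts[b] == 0]
    if empty:
        lo = empty[0] * bin_width
        raise SpliceMapError(
            f"no control candidates in MAF bin [{lo:.2f}, {lo + bin_width:.2f}) "
            f"({sqtl_counts[empty[0]]} sQTL SNP(s) there)"
        )
    s = min(ctrl_counts[b] / sqtl_counts[b] for b in occupied)
    budget = int(np.floor(s * len(sqtl_snps)))
    quotas = {b: s * sqtl_counts[b] for b in occupied}
    take = {b: int(np.floor(q)) for b, q in quotas.items()}
    shortfall = budget - sum(take.values())
    by_remainder = sorted(occupied, key=lambda b: (-(quotas[b] - take[b]), b))
    for b in by_remainder[:shortfall]:
        take[b] += 1

    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    ctrl_ids = np.asarray(control_universe.index)
    for b in occupied:
        pool = ctrl_ids[c_bins == b]
        picked = rng.choice(pool, size=take[b], replace=False)
        chosen.extend(sorted(picked))
    return chosen


def drop_unmatchable(
    sqtl_snps: pd.DataFrame, control_universe: pd.DataFrame, bin_width: float = 0.02
) -> tuple[list[str], list[str]]:
    """Split the sQTL list into (matchable, unmatchable) by MAF bin.

    An sQTL SNP is unmatchable when its 2% MAF bin holds no control
    candidate at all — a small-panel artifact that would make strict
    per-bin matching impossible. Callers decide whether to drop or error.
    """
    if sqtl_snps.empty:
        return [], []
    s_bins = maf_bin_index(sqtl_snps["maf"].to_numpy(), bin_width)
    c_bins = set(maf_bin_index(control_universe["maf"].to_numpy(), bin_width))
    ids = np.asarray(sqtl_snps.index)
    ok = np.array([b in c_bins for b in s_bins])
    return list(ids[ok]), list(ids[~ok])


def expand_locus(
    gwas: GWASPanel,
    index_snp: str,
    genotypes: GenotypeMatrix,
    r2_locus: float = 0.6,
) -> tuple[int, int]:
    """Associated-locus interval: span of SNPs in LD with the index SNP at
    r^2 strictly above r2_locus (singleton interval when none)."""
    if index_snp not in genotypes.snps.index:
        raise SpliceMapError(f"index SNP {index_snp!r} absent from the LD reference panel")
    chrom = genotypes.snps.loc[index_snp, "chrom"]
    on_chrom = genotypes.snps.index[genotypes.snps["chrom"] == chrom]
    positions = [int(genotypes.snps.loc[index_snp, "pos"])]
    for snp in on_chrom:
        if snp == index_snp:
            continue
        try:
            r2 = compute_r2(genotypes, index_snp, snp)
        except UndefinedLDError:
            continue
        if r2 > r2_locus:
            positions.append(int(genotypes.snps.loc[snp, "pos"]))
    return min(positions), max(positions)
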