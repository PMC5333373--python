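"""Functional classification and Fisher-exact enrichment machinery.

SNPs are resolved to a single functional class by precedence over a fixed
13-class order (highest putative impact first); the first 11 classes are
exonic, intron and intergenic are non-exonic. Enrichment of the sQTL set
against the MAF-matched control set is tested with Fisher's exact test on
the 2x2 membership table — two-tailed for functional classes and
regulatory elements, one-tailed (greater) for disease-associated loci —
with Bonferroni correction sized by each test family (10 functional
types; the element types tested; TFs with >= 50,000 annotation records;
15 diseases/traits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .types import AnnotationSet, SpliceMapError, Track

logger = logging.getLogger(__name__)

__all__ = [
    "FUNCTIONAL_CLASSES",
    "EXONIC_CLASSES",
    "NON_EXONIC_CLASSES",
    "LOSS_OF_FUNCTION_POOL",
    "EnrichmentResult",
    "classify_functional",
    "fisher_2x2",
    "enrich_functional",
    "enrich_intervals",
    "enrich_gwas",
    "bonferroni_threshold",
    "MHC_CHROM",
    "MHC_START",
    "MHC_END",
]

# Precedence order, highest impact first.
FUNCTIONAL_CLASSES = (
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
EXONIC_CLASSES = FUNCTIONAL_CLASSES[:11]
NON_EXONIC_CLASSES = FUNCTIONAL_CLASSES[11:]
LOSS_OF_FUNCTION_POOL = ("nonsense", "readthrough", "start-loss", "frameshift")

# The 10-type family tested one class at a time (LoF classes pooled).
FUNCTIONAL_TEST_FAMILY: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("canonical splice site", ("canonical splice site",)),
    ("other loss-of-function", LOSS_OF_FUNCTION_POOL),
    ("missense", ("missense",)),
    ("synonymous", ("synonymous",)),
    ("splice region", ("splice region",)),
    ("5'-UTR", ("5'-UTR",)),
    ("3'-UTR", ("3'-UTR",)),
    ("non-coding exon", ("non-coding exon",)),
    ("intron", ("intron",)),
    ("intergenic", ("intergenic",)),
)

MHC_CHROM = "chr6"
MHC_START = 28_477_797  # hg19, inclusive
MHC_END = 33_448_354  # inclusive

_PRECEDENCE = {label: i for i, label in enumerate(FUNCTIONAL_CLASSES)}


@dataclass
class EnrichmentResult:
    """One Fisher-exact comparison of sQTL vs control membership."""

    test_name: str
    a: int  # sQTL in feature
    b: int  # sQTL not in feature
    c: int  # control in feature
    d: int  # control not in feature
    odds_ratio: float
    ci95: tuple[float, float]
    p: float
    p_adj: float
    family_size: int
    sidedness: str  # "two-tailed" or "one-tailed"

    def as_row(self) -> dict:
        return {
            "test_name": self.test_name,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "odds_ratio": self.odds_ratio,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "p": self.p,
            "p_adj": self.p_adj,
            "family_size": self.family_size,
            "sidedness": self.sidedness,
        }


def classify_functional(snp_labels: dict[str, set[str]] | AnnotationSet, snp_ids) -> pd.Series:
    """Resolve multi-label annotations to one class per SNP by precedence.

    SNPs with no label default to intergenic. Unknown labels raise.
    """
    if isinstance(snp_labels, AnnotationSet):
        snp_labels = snp_labels.labels_for()
    out = {}
    for snp in snp_ids:
        labels = snp_labels.get(snp, set())
        unknown = [lab for lab in labels if lab not in _PRECEDENCE]
        if unknown:
            raise SpliceMapError(f"unknown functional label(s) {unknown} for SNP {snp!r}")
        if labels:
            out[snp] = min(labels, key=_PRECEDENCE.__getitem__)
        else:
            out[snp] = "intergenic"
    return pd.Series(out, name="functional_class").reindex(snp_ids)


def fisher_2x2(
    a: int,
    b: int,
    c: int,
    d: int,
    sidedness: str = "two-tailed",
    estimator: str = "cross-product",
) -> tuple[float, tuple[float, float], float]:
    """Fisher's exact test on [[a, b], [c, d]].

    Returns (odds_ratio, (ci_low, ci_high), p). The two-tailed p sums all
    hypergeometric tables with probability <= the observed one; one-tailed
    tests the "greater" (enrichment) direction. The OR is the sample
    cross-product ratio with a Haldane-Anscombe +0.5 on every cell when any
    cell is zero (``estimator="conditional-mle"`` gives the conditional
    maximum-likelihood OR instead); the 95% CI is the Woolf logit interval
    on the (corrected) table.
    """
    for v in (a, b, c, d):
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise ValueError("cell counts must be non-negative integers")
    if a + b == 0 or c + d == 0:
        raise ValueError("both row margins (set sizes) must be positive")
    if sidedness not in ("two-tailed", "one-tailed"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    alternative = "two-sided" if sidedness == "two-tailed" else "greater"
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative).pvalue)

    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    if estimator == "cross-product":
        odds = (aa * dd) / (bb * cc)
    elif estimator == "conditional-mle":
        odds = float(stats.contingency.odds_ratio([[a, b], [c, d]]).statistic)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    se_log = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    centre = np.log((aa * dd) / (bb * cc))
    ci = (float(np.exp(centre - 1.959963984540054 * se_log)), float(np.exp(centre + 1.959963984540054 * se_log)))
    return odds, ci, p


def _result(
    name: str, a: int, b: int, c: int, d: int, sidedness: str, family_size: int
) -> EnrichmentResult:
    odds, ci, p = fisher_2x2(a, b, c, d, sidedness=sidedness)
    return EnrichmentResult(
        test_name=name,
        a=a,
        b=b,
        c=c,
        d=d,
        odds_ratio=odds,
        ci95=ci,
        p=p,
        p_adj=min(1.0, p * family_size),
        family_size=family_size,
        sidedness=sidedness,
    )


def enrich_functional(
    sqtl_classes: pd.Series, control_classes: pd.Series
) -> list[EnrichmentResult]:
    """Per-class two-tailed tests (10-type family) plus the pooled
    exonic-vs-rest test (its own family of one).

    Inputs are per-SNP functional classes (as from classify_functional).
    Classes empty in both sets are skipped with a log note.
    """
    n_s, n_c = len(sqtl_classes), len(control_classes)
    results: list[EnrichmentResult] = []
    for name, members in FUNCTIONAL_TEST_FAMILY:
        a = int(sqtl_classes.isin(members).sum())
        c = int(control_classes.isin(members).sum())
        if a == 0 and c == 0:
            logger.info("functional class %r empty in both sets; test skipped", name)
            continue
        results.append(_result(name, a, n_s - a, c, n_c - c, "two-tailed", 10))
    a = int(sqtl_classes.isin(EXONIC_CLASSES).sum())
    c = int(control_classes.isin(EXONIC_CLASSES).sum())
    results.append(_result("exonic", a, n_s - a, c, n_c - c, "two-tailed", 1))
    return results


def _membership(track: Track, snp_table: pd.DataFrame) -> np.ndarray:
    """SNP-in-track membership; SNP pos is 1-based, BED half-open, so the
    query point is pos - 1."""
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in track.intervals.groupby("chrom", sort=False):
        tree = IntervalTree()
        for start, end in grp[["start", "end"]].itertuples(index=False):
            if end > start:
                tree.addi(start, end)
        trees[str(chrom)] = tree
    out = np.zeros(len(snp_table), dtype=bool)
    for i, (chrom, pos) in enumerate(snp_table[["chrom", "pos"]].itertuples(index=False)):
        tree = trees.get(str(chrom))
        if tree is not None:
            out[i] = bool(tree.at(int(pos) - 1))
    return out


def enrich_intervals(
    sqtl_table: pd.DataFrame,
    control_table: pd.DataFrame,
    annotations: AnnotationSet,
    tf_min_records: int = 50_000,
) -> list[EnrichmentResult]:
    """Two-tailed membership tests per regulatory track.

    The element family is corrected by the number of element tracks; the
    TF family by the number of TFs retained after excluding tracks with
    fewer than ``tf_min_records`` annotation records.
    """
    elements = [t for t in annotations.tracks.values() if t.family == "element"]
    tfs_all = [t for t in annotations.tracks.values() if t.family == "tf"]
    tfs = [t for t in tfs_all if t.n_records >= tf_min_records]
    dropped = len(tfs_all) - len(tfs)
    if dropped:
        logger.info(
            "excluded %d TF track(s) with < %d records; TF family size %d",
            dropped,
            tf_min_records,
            len(tfs),
        )
    results = []
    for family_tracks, family_size in ((elements, len(elements)), (tfs, len(tfs))):
        for track in sorted(family_tracks, key=lambda t: t.name):
            mem_s = _membership(track, sqtl_table)
            mem_c = _membership(track, control_table)
            a, c = int(mem_s.sum()), int(mem_c.sum())
            results.append(
                _result(
                    track.name,
                    a,
                    len(sqtl_table) - a,
                    c,
                    len(control_table) - c,
                    "two-tailed",
                    family_size,
                )
            )
    return results


def _strip_chr(chrom) -> str:
    s = str(chrom)
    return s[3:] if s.startswith("chr") else s


def _in_mhc(table: pd.DataFrame) -> np.ndarray:
    return (
        (table["chrom"].map(_strip_chr) == _strip_chr(MHC_CHROM))
        & (table["pos"] >= MHC_START)
        & (table["pos"] <= MHC_END)
    ).to_numpy()


def _in_loci(table: pd.DataFrame, loci: pd.DataFrame) -> np.ndarray:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in loci[["chrom", "start", "end"]].itertuples(index=False):
        # Locus intervals are 1-based inclusive; IntervalTree is half-open.
        trees.setdefault(_strip_chr(chrom), IntervalTree()).addi(int(start), int(end) + 1)
    out = np.zeros(len(table), dtype=bool)
    for i, (chrom, pos) in enumerate(table[["chrom", "pos"]].itertuples(index=False)):
        tree = trees.get(_strip_chr(chrom))
        if tree is not None:
            out[i] = bool(tree.at(int(pos)))
    return out


def enrich_gwas(
    sqtl_table: pd.DataFrame,
    control_table: pd.DataFrame,
    loci: pd.DataFrame,
    exclude_mhc: bool = False,
    subset: str = "all",
    test_name: str = "gwas_loci",
    family_size: int = 1,
) -> EnrichmentResult:
    """One-tailed (enrichment) test of membership in disease-associated loci.

    ``subset`` restricts the comparison: "exonic"/"non-exonic" filter both
    sets by functional class; "no-IR" removes sQTL SNPs whose most
    significant AS event is an intron retention (needs a ``best_as_type``
    column). With ``exclude_mhc`` SNPs inside the MHC region are dropped
    from both sets before tabulation.
    """
    s, c = sqtl_table, control_table
    if subset == "exonic":
        s = s[s["functional_class"].isin(EXONIC_CLASSES)]
        c = c[c["functional_class"].isin(EXONIC_CLASSES)]
    elif subset == "non-exonic":
        s = s[s["functional_class"].isin(NON_EXONIC_CLASSES)]
        c = c[c["functional_class"].isin(NON_EXONIC_CLASSES)]
    elif subset == "no-IR":
        s = s[s["best_as_type"] != "IR"]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    if exclude_mhc:
        s = s[~_in_mhc(s)]
        c = c[~_in_mhc(c)]
    if len(s) == 0 or len(c) == 0:
        raise SpliceMapError(f"empty SNP set after subset={subset!r} / MHC filtering")
    a = int(_in_loci(s, loci).sum())
    cc = int(_in_loci(c, loci).sum())
    return _result(test_name, a, len(s) - a, cc, len(c) - cc, "one-tailed", family_size)


def bonferroni_threshold(alpha: float = 0.05, family_size: int = 1) -> float:
    """Family-wise significance threshold alpha / family_size."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return alpha / family_size
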