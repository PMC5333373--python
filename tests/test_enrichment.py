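"""Functional classification, Fisher machinery and the enrichment families."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from splicemap.enrichment import (
    EXONIC_CLASSES,
    FUNCTIONAL_CLASSES,
    MHC_END,
    MHC_START,
    bonferroni_threshold,
    classify_functional,
    enrich_functional,
    enrich_gwas,
    enrich_intervals,
    fisher_2x2,
)
from splicemap.types import AnnotationSet, SpliceMapError, Track

from _oracles import fisher_oracle


# ----------------------------------------------------------- classification


@pytest.mark.parametrize(
    "labels,expected",
    [
        ({"missense", "intron"}, "missense"),
        (set(), "intergenic"),
        ({"canonical splice site", "synonymous", "3'-UTR"}, "canonical splice site"),
        ({"intergenic"}, "intergenic"),
    ],
)
def test_precedence_resolution(labels, expected):
    out = classify_functional({"rs1": labels}, ["rs1"])
    assert out["rs1"] == expected


def test_unknown_label_rejected():
    with pytest.raises(SpliceMapError, match="unknown"):
        classify_functional({"rs1": {"promoter"}}, ["rs1"])


def test_exonic_split_is_a_partition():
    assert len(FUNCTIONAL_CLASSES) == 13
    assert len(EXONIC_CLASSES) == 11
    assert set(FUNCTIONAL_CLASSES) - set(EXONIC_CLASSES) == {"intron", "intergenic"}


# ------------------------------------------------------------------- fisher


def test_exchangeable_table_is_null():
    odds, _, p = fisher_2x2(1, 1, 1, 1)
    assert odds == pytest.approx(1.0) and p == pytest.approx(1.0)


def test_worked_table_or_and_enumeration():
    odds, _, p = fisher_2x2(10, 90, 100, 4800)
    assert odds == pytest.approx(16.0 / 3.0)
    assert p == pytest.approx(fisher_oracle(10, 90, 100, 4800), rel=1e-12)


def test_one_tailed_never_exceeds_two_tailed_for_enriched_tables():
    rng = np.random.default_rng(2)
    checked = 0
    while checked < 50:
        a, b, c, d = (int(x) for x in rng.integers(1, 60, 4))
        if a * d <= b * c:
            continue
        _, _, p2 = fisher_2x2(a, b, c, d, "two-tailed")
        _, _, p1 = fisher_2x2(a, b, c, d, "one-tailed")
        assert p1 <= p2 + 1e-12
        checked += 1


def test_random_tables_match_exact_enumeration():
    rng = np.random.default_rng(7)
    done = 0
    while done < 200:
        a, b, c, d = (int(x) for x in rng.integers(0, 101, 4))
        if a + b == 0 or c + d == 0:
            continue
        for side in ("two-tailed", "one-tailed"):
            _, _, p = fisher_2x2(a, b, c, d, side)
            assert p == pytest.approx(fisher_oracle(a, b, c, d, side), rel=1e-12, abs=1e-300)
        done += 1


def test_row_swap_inverts_or_and_preserves_p():
    rng = np.random.default_rng(11)
    for _ in range(30):
        a, b, c, d = (int(x) for x in rng.integers(1, 80, 4))
        o1, _, p1 = fisher_2x2(a, b, c, d)
        o2, _, p2 = fisher_2x2(c, d, a, b)
        assert o2 == pytest.approx(1.0 / o1)
        assert p2 == pytest.approx(p1, rel=1e-12)


def test_zero_set_margin_is_an_error():
    with pytest.raises(ValueError, match="margin"):
        fisher_2x2(0, 0, 5, 5)


def test_zero_cell_uses_haldane_anscombe():
    odds, ci, _ = fisher_2x2(5, 0, 3, 7)
    assert odds == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))
    assert ci[0] < odds < ci[1]


def test_conditional_mle_estimator_available():
    odds_cp, _, _ = fisher_2x2(10, 90, 100, 4800)
    odds_ml, _, _ = fisher_2x2(10, 90, 100, 4800, estimator="conditional-mle")
    assert odds_ml == pytest.approx(odds_cp, rel=0.15)  # close but not equal
    assert odds_ml != odds_cp


# ------------------------------------------------------- functional family


def _classes(counts: dict[str, int], prefix: str) -> pd.Series:
    vals = []
    for label, n in counts.items():
        vals.extend([label] * n)
    return pd.Series(vals, index=[f"{prefix}{i}" for i in range(len(vals))])


def test_identity_comparison_is_null():
    classes = _classes({"missense": 5, "intron": 30, "intergenic": 25}, "s")
    results = enrich_functional(classes, classes.copy())
    for r in results:
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.p == pytest.approx(1.0)


def test_family_sizes_and_adjustment():
    sq = _classes({"missense": 10, "intron": 60, "intergenic": 30}, "s")
    ct = _classes({"missense": 10, "intron": 600, "intergenic": 390}, "c")
    results = {r.test_name: r for r in enrich_functional(sq, ct)}
    for name, r in results.items():
        expected_family = 1 if name == "exonic" else 10
        assert r.family_size == expected_family
        assert r.p_adj == pytest.approx(min(1.0, r.p * expected_family))


def test_planted_exonic_enrichment_detected_at_study_scale():
    """sQTLs 3x enriched in exonic labels at 1,500 / 48,000 scale."""
    rng = np.random.default_rng(21)
    sq = pd.Series(
        np.where(rng.random(1500) < 0.15, "missense", "intron"),
        index=[f"s{i}" for i in range(1500)],
    )
    ct = pd.Series(
        np.where(rng.random(48000) < 0.05, "missense", "intron"),
        index=[f"c{i}" for i in range(48000)],
    )
    pooled = [r for r in enrich_functional(sq, ct) if r.test_name == "exonic"][0]
    assert pooled.odds_ratio > 1.0
    assert pooled.p_adj < 0.05


def test_pooled_exonic_count_partitions():
    rng = np.random.default_rng(3)
    classes = pd.Series(
        rng.choice(FUNCTIONAL_CLASSES, 500), index=[f"s{i}" for i in range(500)]
    )
    per_class = sum(int((classes == c).sum()) for c in EXONIC_CLASSES)
    assert per_class == int(classes.isin(EXONIC_CLASSES).sum())


# ------------------------------------------------------------ interval tests


def _snp_table(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "maf"], index=pd.Index([f"r{i}" for i in range(len(rows))])
    )


def _one_track_annotations(intervals, n_records=None, family="element", name="T"):
    iv = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    track = Track(name=name, family=family, intervals=iv,
                  n_records=len(iv) if n_records is None else n_records)
    return AnnotationSet(pd.DataFrame(columns=["snp_id", "label"]), {name: track})


@pytest.mark.parametrize("start,end,member", [(100, 101, True), (101, 200, False)])
def test_bed_half_open_against_1_based_pos(start, end, member):
    """1-based pos 101 is BED point 100: member iff 100 in [start, end)."""
    ann = _one_track_annotations([("chr1", start, end)])
    sq = _snp_table([("chr1", 101, 0.3)])
    ct = _snp_table([("chr1", 5000, 0.3)] * 5)
    res = enrich_intervals(sq, ct, ann, tf_min_records=0)[0]
    assert res.a == (1 if member else 0)


def test_whole_chromosome_track_degenerates_gracefully():
    ann = _one_track_annotations([("chr1", 0, 10_000_000)])
    sq = _snp_table([("chr1", 100, 0.3), ("chr1", 200, 0.2)])
    ct = _snp_table([("chr1", 300, 0.3), ("chr1", 400, 0.2)])
    res = enrich_intervals(sq, ct, ann, tf_min_records=0)[0]
    assert res.p == pytest.approx(1.0)
    assert np.isfinite(res.odds_ratio)


@pytest.mark.parametrize("n_records,expect_tested", [(49_999, 0), (50_000, 1)])
def test_tf_record_threshold_boundary(n_records, expect_tested):
    ann = _one_track_annotations(
        [("chr1", 100, 200)], n_records=n_records, family="tf", name="POLR2A"
    )
    sq = _snp_table([("chr1", 150, 0.3)])
    ct = _snp_table([("chr1", 5000, 0.3)] * 3)
    results = enrich_intervals(sq, ct, ann)
    assert len(results) == expect_tested
    if expect_tested:
        assert results[0].family_size == 1


def test_tf_family_size_counts_retained_tracks_only():
    iv = [("chr1", 100, 200)]
    tracks = {}
    for name, nrec in (("A", 60_000), ("B", 70_000), ("C", 10_000)):
        tracks[name] = Track(name=name, family="tf",
                             intervals=pd.DataFrame(iv, columns=["chrom", "start", "end"]),
                             n_records=nrec)
    ann = AnnotationSet(pd.DataFrame(columns=["snp_id", "label"]), tracks)
    sq = _snp_table([("chr1", 150, 0.3), ("chr1", 5000, 0.2)])
    ct = _snp_table([("chr1", 5000, 0.3)] * 4)
    results = enrich_intervals(sq, ct, ann)
    assert {r.test_name for r in results} == {"A", "B"}
    assert all(r.family_size == 2 for r in results)


# ----------------------------------------------------------------- gwas test


def _gwas_sets():
    sq = pd.DataFrame(
        {
            "chrom": ["chr6"] * 4 + ["chr2"] * 6,
            "pos": [MHC_START, MHC_START - 1, 100, 200] + list(range(1000, 7000, 1000)),
            "maf": 0.3,
            "functional_class": ["intron"] * 5 + ["missense"] * 5,
            "best_as_type": ["IR", "AltEX"] * 5,
        },
        index=[f"s{i}" for i in range(10)],
    )
    ct = sq.copy()
    ct.index = [f"c{i}" for i in range(10)]
    loci = pd.DataFrame(
        [("L1", "chr2", 500, 2500, "")], columns=["locus_id", "chrom", "start", "end", "index_snp"]
    )
    return sq, ct, loci


def test_mhc_mask_boundary_is_inclusive():
    sq, ct, loci = _gwas_sets()
    res = enrich_gwas(sq, ct, loci, exclude_mhc=True)
    # MHC_START row dropped from both sets; MHC_START-1 retained
    assert res.a + res.b == 9
    res_keep = enrich_gwas(sq, ct, loci, exclude_mhc=False)
    assert res_keep.a + res_keep.b == 10


def test_subsets_restrict_the_comparison():
    sq, ct, loci = _gwas_sets()
    non_exonic = enrich_gwas(sq, ct, loci, subset="non-exonic")
    assert non_exonic.a + non_exonic.b == 5
    exonic = enrich_gwas(sq, ct, loci, subset="exonic")
    assert exonic.a + exonic.b == 5
    no_ir = enrich_gwas(sq, ct, loci, subset="no-IR")
    assert no_ir.a + no_ir.b == 5  # IR-best sQTLs dropped
    assert no_ir.c + no_ir.d == 10  # control set untouched


def test_empty_loci_membership_is_null():
    sq, ct, _ = _gwas_sets()
    loci = pd.DataFrame(
        [("L1", "chr9", 10, 20, "")], columns=["locus_id", "chrom", "start", "end", "index_snp"]
    )
    res = enrich_gwas(sq, ct, loci)
    assert res.a == 0 and res.c == 0
    assert res.p == pytest.approx(1.0)


def test_permuted_labels_control_type_i_error():
    """Swapping set labels at random keeps each family's Bonferroni-level
    false-positive rate at or below alpha."""
    rng = np.random.default_rng(17)
    pool_class = pd.Series(
        rng.choice(["missense", "intron", "intergenic"], 600, p=[0.1, 0.5, 0.4]),
        index=[f"x{i}" for i in range(600)],
    )
    alpha = 0.05
    hits = 0
    reps = 200
    for _ in range(reps):
        perm = rng.permutation(600)
        sq = pool_class.iloc[perm[:100]]
        ct = pool_class.iloc[perm[100:]]
        results = [r for r in enrich_functional(sq, ct) if r.family_size == 10]
        thr = bonferroni_threshold(alpha, 10)
        if any(r.p < thr for r in results):
            hits += 1
    assert hits / reps <= alpha + 0.02


# ------------------------------------------------------------- thresholds


def test_printed_bonferroni_thresholds():
    # compared at the 2-significant-figure precision the thresholds are
    # conventionally printed at
    assert bonferroni_threshold(0.05, 65) == pytest.approx(7.7e-4, abs=5e-6)
    assert bonferroni_threshold(0.05, 15) == pytest.approx(0.0033, abs=5e-5)
    assert bonferroni_threshold(0.05, 1) == 0.05


def test_invalid_family_size_rejected():
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)


@given(st.integers(min_value=1, max_value=10_000))
def test_threshold_scales_inversely(m):
    assert bonferroni_threshold(0.05, m) == pytest.approx(0.05 / m)
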