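"""Additive-model fits, BH adjustment and the double-corrected sQTL calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from splicemap import mapping
from splicemap.mapping import (
    InsufficientDataError,
    ZeroVarianceError,
    benjamini_hochberg,
    best_sqtl_per_event,
    call_sqtl_snps,
    count_local_events,
    fit_additive_model,
    map_cis_pairs,
)

from _oracles import bh_oracle, cis_pairs_oracle, ols_oracle
from conftest import toy_covariates, toy_events, toy_genotypes


# ------------------------------------------------------------------ OLS fit


def _random_fixture(rng, n, k):
    g = rng.integers(0, 3, size=n).astype(float)
    while np.ptp(g) == 0:
        g = rng.integers(0, 3, size=n).astype(float)
    cov = rng.normal(size=(n, k)) if k else None
    y = 50 + 3 * g + rng.normal(scale=5, size=n)
    if k:
        y = y + cov @ rng.normal(size=k)
    return np.clip(y, 0, 100), g, cov


def test_fit_matches_normal_equations_oracle_on_many_fixtures():
    """beta/se/t/p equal an explicit-inversion OLS on 120 random fixtures."""
    rng = np.random.default_rng(42)
    for _ in range(120):
        n = int(rng.integers(12, 201))
        k = int(rng.integers(0, 5))
        y, g, cov = _random_fixture(rng, n, k)
        fit = fit_additive_model(y, g, cov)
        beta, se, t, p = ols_oracle(y, g, cov)
        np.testing.assert_allclose(
            [fit.beta, fit.se, fit.t_stat, fit.p], [beta, se, t, p], rtol=1e-10
        )


def test_printed_small_fixture_matches_oracle():
    y = np.array([41.0, 55.0, 62.0, 48.0, 39.0, 71.0, 66.0, 52.0, 45.0, 58.0, 60.0, 49.0])
    g = np.array([0.0, 1.0, 2.0, 0.0, 0.0, 2.0, 2.0, 1.0, 0.0, 1.0, 2.0, 1.0])
    cov = np.array([[1.2], [0.4], [-0.3], [2.1], [0.0], [-1.1], [0.7], [0.9], [1.5], [-0.2], [0.3], [0.8]])
    fit = fit_additive_model(y, g, cov)
    beta, se, t, p = ols_oracle(y, g, cov)
    np.testing.assert_allclose([fit.beta, fit.se, fit.t_stat, fit.p], [beta, se, t, p], rtol=1e-10)


def test_constant_psi_gives_null_result():
    fit = fit_additive_model(np.full(20, 50.0), np.tile([0.0, 1.0], 10))
    assert fit.beta == 0.0 and fit.p == 1.0


def test_joint_permutation_of_samples_is_invariant():
    rng = np.random.default_rng(1)
    y, g, cov = _random_fixture(rng, 60, 2)
    perm = rng.permutation(60)
    a = fit_additive_model(y, g, cov)
    b = fit_additive_model(y[perm], g[perm], cov[perm])
    np.testing.assert_allclose([a.beta, a.se, a.t_stat, a.p], [b.beta, b.se, b.t_stat, b.p], rtol=1e-12)


def test_zero_dosage_variance_raises():
    with pytest.raises(ZeroVarianceError):
        fit_additive_model(np.arange(20.0), np.ones(20))


def test_too_few_samples_raises():
    with pytest.raises(InsufficientDataError):
        fit_additive_model(np.arange(5.0), np.array([0, 1, 2, 0, 1.0]))


def test_missing_psi_dropped_missing_dosage_imputed():
    rng = np.random.default_rng(4)
    y, g, cov = _random_fixture(rng, 80, 1)
    y2, g2 = y.copy(), g.copy()
    y2[:5] = np.nan
    g2[10:13] = np.nan
    fit = fit_additive_model(y2, g2, cov)
    g_imp = g2.copy()
    g_imp[np.isnan(g_imp)] = np.nanmean(g2)
    beta, se, t, p = ols_oracle(y[5:], g_imp[5:], cov[5:])
    np.testing.assert_allclose([fit.beta, fit.se, fit.t_stat, fit.p], [beta, se, t, p], rtol=1e-10)
    assert fit.n_used == 75


# ---------------------------------------------------------------- cis pairs


def _toy_panel():
    """5 SNPs x 4 events with printed coordinates around a 100 kb window."""
    rng = np.random.default_rng(9)
    dosages = {f"rs{i}": rng.integers(0, 3, 40).astype(float) for i in range(1, 6)}
    positions = [50_000, 140_000, 260_000, 390_000, 610_000]
    geno = toy_genotypes(dosages, positions=positions)
    samples = geno.samples
    rows = [
        ("EV1", "chr1", 100_000, 101_000),
        ("EV2", "chr1", 240_000, 241_500),
        ("EV3", "chr1", 480_000, 480_400),
        ("EV4", "chr1", 700_000, 700_900),
    ]
    psi = np.clip(rng.normal(50, 10, size=(4, 40)), 0, 100)
    events = toy_events(rows, samples, psi)
    return geno, events, toy_covariates(samples)


def test_pair_enumeration_matches_brute_force():
    geno, events, cov = _toy_panel()
    pairs = map_cis_pairs(geno, events, cov)
    got = set(zip(pairs["snp_id"], pairs["event_id"]))
    expected = cis_pairs_oracle(geno.snps, events.events)
    assert got == expected
    # spot checks from the printed coordinates
    assert ("rs1", "EV1") in got  # 50 kb away
    assert ("rs5", "EV3") not in got  # 129,600 bp gap
    assert ("rs5", "EV4") in got  # 90,000 bp gap


def test_pair_stats_match_single_fit_route():
    """The vectorised residualisation equals the per-pair OLS fit."""
    geno, events, cov = _toy_panel()
    pairs = map_cis_pairs(geno, events, cov)
    design, _ = cov.design_matrix()
    for row in pairs.itertuples():
        y = events.psi.loc[row.event_id].to_numpy()
        g = geno.dosage.loc[row.snp_id].to_numpy()
        fit = fit_additive_model(y, g, design)
        np.testing.assert_allclose(
            [row.beta, row.se, row.t, row.p], [fit.beta, fit.se, fit.t_stat, fit.p], rtol=1e-9
        )


def test_snp_without_local_event_absent(small_dataset):
    from splicemap.filtering import filter_as_events, filter_snps

    events, _ = filter_as_events(small_dataset.events)
    geno = filter_snps(small_dataset.genotypes, events)
    pairs = map_cis_pairs(geno, events, small_dataset.covariates)
    n_local = count_local_events(geno, events)
    assert set(pairs["snp_id"]) <= set(n_local.index[n_local > 0])


# ----------------------------------------------------------------------- BH


def test_bh_identity_for_single_test():
    np.testing.assert_allclose(benjamini_hochberg([0.037]), [0.037])


def test_bh_equal_pvalues_stay_put():
    np.testing.assert_allclose(benjamini_hochberg([0.2] * 7), [0.2] * 7)


def test_bh_stepup_worked_example():
    np.testing.assert_allclose(
        benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )


def test_bh_rejects_out_of_range():
    for bad in ([0.0, 0.5], [0.5, 1.2], [np.nan, 0.5]):
        with pytest.raises(ValueError):
            benjamini_hochberg(bad)


@given(
    st.lists(st.floats(min_value=1e-12, max_value=1.0, exclude_min=False), min_size=1, max_size=60)
)
def test_bh_matches_literal_stepup_and_statsmodels(pvals):
    p = np.asarray(pvals)
    ours = benjamini_hochberg(p)
    np.testing.assert_allclose(ours, bh_oracle(p), rtol=1e-12)
    sm = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(ours, sm, rtol=1e-9, atol=1e-12)
    # monotone in p
    order = np.argsort(p)
    assert (np.diff(ours[order]) >= -1e-15).all()


def test_bh_on_chunks_differs_from_joint_adjustment():
    """Adjusting per chunk is NOT the same as adjusting the pooled list."""
    rng = np.random.default_rng(3)
    p = np.sort(rng.uniform(1e-6, 1.0, 40))
    joint = benjamini_hochberg(p)
    chunked = np.concatenate([benjamini_hochberg(p[:20]), benjamini_hochberg(p[20:])])
    assert not np.allclose(joint, chunked)


# ------------------------------------------------------------- sQTL calls


def _calls_fixture(small_dataset):
    from splicemap.filtering import filter_as_events, filter_snps

    events, _ = filter_as_events(small_dataset.events)
    geno = filter_snps(small_dataset.genotypes, events)
    pairs = map_cis_pairs(geno, events, small_dataset.covariates)
    calls = call_sqtl_snps(pairs, geno, events)
    return geno, events, pairs, calls


@pytest.mark.parametrize(
    "min_p_bh,n_events,expect_p,expect_call",
    [(0.004, 10, 0.04, True), (0.3, 5, 1.0, False)],
)
def test_double_correction_arithmetic(min_p_bh, n_events, expect_p, expect_call):
    rng = np.random.default_rng(0)
    geno = toy_genotypes({"rs1": rng.integers(0, 3, 40).astype(float)}, positions=[100_000])
    rows = [(f"EV{i}", "chr1", 100_000 + 100 * i, 100_050 + 100 * i) for i in range(n_events)]
    psi = np.clip(rng.normal(50, 10, size=(n_events, 40)), 0, 100)
    events = toy_events(rows, geno.samples, psi)
    p_bh = np.linspace(min_p_bh, min(1.0, min_p_bh * 3), n_events)
    pairs = pd.DataFrame(
        {
            "snp_id": "rs1",
            "event_id": [r[0] for r in rows],
            "beta": 1.0,
            "se": 0.5,
            "t": 2.0,
            "p": p_bh / 2,
            "p_bh": p_bh,
            "distance_bp": 0,
        }
    )
    calls = call_sqtl_snps(pairs, geno, events)
    assert calls.loc["rs1", "p_double"] == pytest.approx(expect_p)
    assert bool(calls.loc["rs1", "is_sqtl"]) is expect_call
    assert calls.loc["rs1", "n_local_events"] == n_events


def test_call_invariants_hold(small_dataset):
    geno, events, pairs, calls = _calls_fixture(small_dataset)
    assert (calls["min_p_bh"] >= calls["min_p_raw"]).all()
    assert (calls["p_double"] >= calls["min_p_bh"] - 1e-15).all()
    assert (calls["p_double"] <= 1.0).all()
    assert ((calls["p_double"] < 0.05) == calls["is_sqtl"]).all()
    assert (calls["n_local_events"] >= 1).all()
    # p_double cap: construct a SNP with min_p_bh * n > 1
    capped = calls[calls["min_p_bh"] * calls["n_local_events"] > 1.0]
    assert (capped["p_double"] == 1.0).all()


def test_local_event_count_counts_events_not_tests(small_dataset):
    geno, events, pairs, calls = _calls_fixture(small_dataset)
    oracle = cis_pairs_oracle(geno.snps, events.events)
    for snp in calls.index[:40]:
        expected = sum(1 for s, _ in oracle if s == snp)
        assert calls.loc[snp, "n_local_events"] == expected


def test_pure_noise_event_changes_bonferroni_count_not_pair_p(small_dataset):
    """A far-away noise event leaves every pair p unchanged but raises the
    local Bonferroni multiplier (hence p_double) of SNPs in its window."""
    from splicemap.filtering import filter_as_events, filter_snps
    from splicemap.types import ASEventTable

    events, _ = filter_as_events(small_dataset.events)
    geno = filter_snps(small_dataset.genotypes, events)
    pairs_before = map_cis_pairs(geno, events, small_dataset.covariates)
    calls_before = call_sqtl_snps(pairs_before, geno, events)

    rng = np.random.default_rng(0)
    target_snp = calls_before.index[len(calls_before) // 2]
    target_pos = int(geno.snps.loc[target_snp, "pos"])
    new_meta = events.events.iloc[:1].copy()
    new_meta.index = pd.Index(["EV_NOISE"], name="event_id")
    new_meta.loc["EV_NOISE", ["span_start", "span_end"]] = [target_pos + 10, target_pos + 500]
    noise_psi = pd.DataFrame(
        np.clip(rng.normal(50, 8, size=(1, len(events.samples))), 0, 100),
        index=new_meta.index,
        columns=events.samples,
    )
    noise_ok = pd.DataFrame(True, index=new_meta.index, columns=events.samples)
    extended = ASEventTable(
        pd.concat([events.events, new_meta]),
        pd.concat([events.psi, noise_psi]),
        pd.concat([events.quality_ok, noise_ok]),
    )
    pairs_after = map_cis_pairs(geno, extended, small_dataset.covariates)
    calls_after = call_sqtl_snps(pairs_after, geno, extended)

    merged = pairs_before.merge(
        pairs_after, on=["snp_id", "event_id"], suffixes=("_b", "_a")
    )
    np.testing.assert_allclose(merged["p_b"], merged["p_a"], rtol=1e-12)
    assert (
        calls_after.loc[target_snp, "n_local_events"]
        == calls_before.loc[target_snp, "n_local_events"] + 1
    )


def test_best_per_event_tiebreaks_and_oracle(small_dataset):
    geno, events, pairs, calls = _calls_fixture(small_dataset)
    best = best_sqtl_per_event(pairs, calls)
    sqtl_ids = set(calls.index[calls["is_sqtl"]])
    # brute-force argmin oracle
    for event_id, snp_id in best.itertuples(index=False):
        cand = pairs[(pairs["event_id"] == event_id) & pairs["snp_id"].isin(sqtl_ids)]
        cand = cand.sort_values(["p", "distance_bp", "snp_id"], kind="stable")
        assert cand.iloc[0]["snp_id"] == snp_id
    # explicit tie fixture: equal p, distances 500 and 2000
    pairs_tie = pd.DataFrame(
        {
            "snp_id": ["rsA", "rsB"],
            "event_id": ["EV1", "EV1"],
            "beta": [1.0, 1.0],
            "se": [0.1, 0.1],
            "t": [10.0, 10.0],
            "p": [1e-6, 1e-6],
            "p_bh": [1e-5, 1e-5],
            "distance_bp": [2000, 500],
        }
    )
    calls_tie = pd.DataFrame(
        {"is_sqtl": [True, True]}, index=pd.Index(["rsA", "rsB"], name="snp_id")
    )
    out = best_sqtl_per_event(pairs_tie, calls_tie)
    assert list(out.itertuples(index=False)) == [("EV1", "rsB")]
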