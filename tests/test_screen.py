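import numpy as np
import pandas as pd
import pytest
import scipy.stats
from statsmodels.stats.multitest import multipletests

import bdrscreen as b
from bdrscreen.errors import DomainError
from bdrscreen.screen import (
    bh_adjust,
    metabolite_age_trend,
    percent_significant,
    qq_points,
    replication_report,
    run_cross_sectional_screen,
    run_longitudinal_screen,
    stratified_screen,
)

CLEAN_LCMS = b.LcmsSpec(drift_amplitude=0, missing_rate=0, tech_sigma=0, snr_log_sd=0)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def test_bh_worked_example_family_501():
    """Top p = 1.77e-4 in a family of 501 adjusts to 0.089 at 3 decimals."""
    p = np.concatenate([[1.77e-4], np.linspace(0.2, 1.0, 500)])
    q = bh_adjust(p)
    assert round(q[0], 3) == 0.089


def test_bh_hand_computed_min_cumulative():
    assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])


def test_bh_cap_at_one():
    assert bh_adjust([1.0]) == pytest.approx([1.0])


def test_bh_domain_error():
    with pytest.raises(DomainError):
        bh_adjust([0.5, 1.2])


def test_bh_matches_statsmodels_reference():
    """Exact agreement with an independent step-up implementation on many
    random p-vectors."""
    rng = np.random.default_rng(0)
    for _ in range(200):
        p = rng.random(rng.integers(1, 60))
        ours = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.max(np.abs(ours - ref)) <= 1e-12


def test_bh_monotone_when_sorted():
    rng = np.random.default_rng(1)
    p = np.sort(rng.random(100))
    q = bh_adjust(p)
    assert np.all(np.diff(q) >= -1e-15)


def test_percent_significant_printed_fractions():
    """39/501 -> 7.8% and 12/615 -> 2.0% at one decimal."""
    def fake_results(k, m):
        p = np.concatenate([np.full(k, 0.01), np.full(m - k, 0.5)])
        return pd.DataFrame({"p": p, "status": "ok"})

    assert f"{percent_significant(fake_results(39, 501)):.1f}" == "7.8"
    assert f"{percent_significant(fake_results(12, 615)):.1f}" == "2.0"


# ---------------------------------------------------------------------------
# screens on simulated cohorts
# ---------------------------------------------------------------------------

def _sim_screen(seed, **kw):
    cfg = b.SimConfig(**kw, seed=seed)
    cohort, fm, truth = b.simulate_cohort(cfg)
    proc, _ = b.preprocess(fm)
    return cohort, proc, truth


def test_longitudinal_screen_ranks_active_features():
    """Planted interactions (beta 0.01, 5 of 50 features, 400 subjects)
    dominate the top of the screen."""
    hits = 0
    for seed in range(3):
        cohort, proc, truth = _sim_screen(
            seed, n_subjects=400, n_features=50, frac_active=0.10,
            beta_int_active=0.01, lcms=CLEAN_LCMS,
        )
        res = run_longitudinal_screen(cohort, proc)
        active = set(truth.feature_table.index[truth.feature_table.active])
        hits += active <= set(res["feature_id"].head(10))
    assert hits == 3


def test_longitudinal_screen_null_calibration():
    """With no active features the p < 0.05 fraction is near nominal."""
    cohort, proc, _ = _sim_screen(11, n_subjects=300, n_features=500, frac_active=0.0)
    res = run_longitudinal_screen(cohort, proc)
    frac = (res.loc[res["status"] == "ok", "p"] < 0.05).mean()
    assert 0.03 <= frac <= 0.07


def test_screen_results_contract():
    cohort, proc, _ = _sim_screen(2, n_subjects=80, n_features=20, frac_active=0.0)
    res = run_longitudinal_screen(cohort, proc)
    ok = res[res["status"] == "ok"]
    assert ((ok["p"] >= 0) & (ok["p"] <= 1)).all()
    assert (ok["q"] >= ok["p"] - 1e-15).all()
    assert (ok["q"] <= 1).all()
    assert ok["p"].is_monotonic_increasing
    assert set(res["feature_id"]) == set(proc.feature_ids)


def test_screen_invariant_to_feature_and_row_order():
    cohort, proc, _ = _sim_screen(3, n_subjects=60, n_features=12, frac_active=0.0)
    res = run_longitudinal_screen(cohort, proc)
    rng = np.random.default_rng(0)
    z = proc.study_frame()
    z_shuf = z.iloc[rng.permutation(len(z))]
    cohort_shuf = cohort.iloc[rng.permutation(len(cohort))].reset_index(drop=True)
    res2 = run_longitudinal_screen(cohort_shuf, z_shuf)
    merged = res.merge(res2, on="feature_id", suffixes=("_a", "_b"))
    assert merged["beta_a"].to_numpy() == pytest.approx(merged["beta_b"].to_numpy(), abs=1e-8)
    assert merged["p_a"].to_numpy() == pytest.approx(merged["p_b"].to_numpy(), abs=1e-6)


def test_longitudinal_collapses_to_ols_for_singleton_subjects():
    """All-singleton subjects: mixed-model betas/SEs equal the per-feature
    OLS screen on the same data."""
    cfg = b.SimConfig.gacrs_like(n_subjects=150, n_features=5, frac_active=0.0,
                                 lcms=CLEAN_LCMS, seed=4)
    cohort, fm, _ = b.simulate_cross_sectional(cfg)
    proc, _ = b.preprocess(fm)
    lon = run_longitudinal_screen(cohort, proc, covariates=("sex",))
    cross = run_cross_sectional_screen(cohort, proc, covariates=("sex",))
    m = lon.merge(cross, on="feature_id", suffixes=("_l", "_c"))
    assert m["beta_l"].to_numpy() == pytest.approx(m["beta_c"].to_numpy(), rel=1e-6)
    assert m["se_l"].to_numpy() == pytest.approx(m["se_c"].to_numpy(), rel=1e-6)


def test_cross_sectional_recovery():
    """Known interaction of 0.02 in a single-visit cohort is recovered on
    average (documented scale-down: 25 seeds)."""
    ests = []
    for seed in range(25):
        cfg = b.SimConfig.gacrs_like(
            n_subjects=320, n_features=1, frac_active=1.0,
            beta_int_active=0.02, lcms=CLEAN_LCMS, seed=100 + seed,
        )
        cohort, fm, _ = b.simulate_cross_sectional(cfg)
        proc, _ = b.preprocess(fm)
        res = run_cross_sectional_screen(cohort, proc)
        ests.append(res["beta"].iloc[0])
    assert np.mean(ests) == pytest.approx(0.02, rel=0.10)


def test_cross_sectional_null_p_uniform():
    """Null features: interaction p-values are uniform (KS at 0.01)."""
    cfg = b.SimConfig.gacrs_like(n_subjects=200, n_features=300, frac_active=0.0,
                                 lcms=CLEAN_LCMS, seed=7)
    cohort, fm, _ = b.simulate_cross_sectional(cfg)
    proc, _ = b.preprocess(fm)
    res = run_cross_sectional_screen(cohort, proc)
    ks = scipy.stats.kstest(res.loc[res["status"] == "ok", "p"], "uniform")
    assert ks.pvalue > 0.01


def test_duplicating_rows_shrinks_se():
    cfg = b.SimConfig.gacrs_like(n_subjects=100, n_features=3, frac_active=0.0,
                                 lcms=CLEAN_LCMS, seed=8)
    cohort, fm, _ = b.simulate_cross_sectional(cfg)
    proc, _ = b.preprocess(fm)
    res1 = run_cross_sectional_screen(cohort, proc)
    doubled = pd.concat([cohort, cohort.assign(subject_id=cohort.subject_id + "_d",
                                               visit="dup")], ignore_index=True)
    res2 = run_cross_sectional_screen(doubled, proc)
    m = res1.merge(res2, on="feature_id", suffixes=("_1", "_2"))
    assert m["beta_1"].to_numpy() == pytest.approx(m["beta_2"].to_numpy(), rel=1e-8)
    assert (m["se_2"] < m["se_1"]).all()


def test_single_level_covariate_dropped(caplog):
    """Race in a single-race cohort is dropped from the design, not an error."""
    cfg = b.SimConfig.gacrs_like(n_subjects=80, n_features=2, frac_active=0.0,
                                 lcms=CLEAN_LCMS, seed=9)
    cohort, fm, _ = b.simulate_cross_sectional(cfg)
    proc, _ = b.preprocess(fm)
    with caplog.at_level("INFO"):
        res = run_cross_sectional_screen(cohort, proc, covariates=("race", "sex"))
    assert (res["status"] == "ok").all()
    assert any("single level" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# replication
# ---------------------------------------------------------------------------

def _screen_row(fid, beta, p):
    return {"feature_id": fid, "beta": beta, "p": p}


def test_replication_tiers_worked_examples():
    """The three printed discovery/replication pairs map to
    replicated / nominal / not_replicated."""
    disc = pd.DataFrame([
        _screen_row("2-hydroxyglutarate", -0.004, 1.8e-4),
        _screen_row("GABA", 0.004, 0.004),
        _screen_row("C36:1 DAG", -0.002, 0.011),
    ])
    rep = pd.DataFrame([
        _screen_row("2-hydroxyglutarate", -0.015, 0.018),
        _screen_row("GABA", 0.01, 0.085),
        _screen_row("C36:1 DAG", 0.001, 0.823),
    ])
    out = replication_report(disc, rep).set_index("feature_id")
    assert out.loc["2-hydroxyglutarate", "tier"] == "replicated"
    assert out.loc["GABA", "tier"] == "nominal"
    assert out.loc["C36:1 DAG", "tier"] == "not_replicated"
    assert not out.loc["C36:1 DAG", "direction_consistent"]


def test_replication_untested_and_partition():
    disc = pd.DataFrame([_screen_row("a", 0.1, 0.01), _screen_row("b", 0.1, 0.01)])
    rep = pd.DataFrame([_screen_row("a", 0.2, 0.2)])
    out = replication_report(disc, rep)
    tiers = dict(zip(out["feature_id"], out["tier"]))
    assert tiers["b"] == "untested"
    assert tiers["a"] == "not_replicated"
    assert out["tier"].isin(["replicated", "nominal", "not_replicated", "untested"]).all()


def test_replication_disjoint_all_untested():
    disc = pd.DataFrame([_screen_row("a", 0.1, 0.01)])
    rep = pd.DataFrame([_screen_row("z", 0.2, 0.2)])
    out = replication_report(disc, rep)
    assert (out["tier"] == "untested").all()


# ---------------------------------------------------------------------------
# stratified screens and trends
# ---------------------------------------------------------------------------

def test_stratified_identical_strata_match():
    cfg = b.SimConfig(n_subjects=60, n_features=4, frac_active=0.0,
                      lcms=CLEAN_LCMS, seed=12)
    cohort, fm, _ = b.simulate_cohort(cfg)
    proc, _ = b.preprocess(fm)
    # duplicate the cohort into two identical strata
    c2 = cohort.assign(subject_id=cohort.subject_id + "_b", stratvar="g2",
                       sample_id=cohort.sample_id)
    both = pd.concat([cohort.assign(stratvar="g1"), c2], ignore_index=True)
    res, skipped = stratified_screen(both, proc, "stratvar", covariates=("sex",))
    g1 = res[res["stratum"] == "g1"].set_index("feature_id")
    g2 = res[res["stratum"] == "g2"].set_index("feature_id")
    assert g1["beta"].to_numpy() == pytest.approx(g2["beta"].to_numpy(), abs=1e-10)
    assert skipped == []


def test_stratified_small_stratum_skipped():
    cfg = b.SimConfig(n_subjects=60, n_features=2, frac_active=0.0,
                      lcms=CLEAN_LCMS, seed=13)
    cohort, fm, _ = b.simulate_cohort(cfg)
    proc, _ = b.preprocess(fm)
    cohort = cohort.assign(stratvar="big")
    cohort.loc[cohort.index[:5], "stratvar"] = "tiny"
    res, skipped = stratified_screen(cohort, proc, "stratvar", covariates=("sex",))
    assert skipped == ["tiny"]
    assert set(res["stratum"]) == {"big"}


def test_sex_specific_effect_detected_in_right_stratum():
    """An interaction planted in males only yields a smaller male-stratum p
    in most seeds."""
    wins = 0
    for seed in range(10):
        cfg = b.SimConfig(n_subjects=400, n_features=1, frac_active=1.0,
                          beta_int_active=0.012, lcms=CLEAN_LCMS, seed=600 + seed)
        cohort, fm, truth = b.simulate_cohort(cfg)
        proc, _ = b.preprocess(fm)
        # remove the planted signal from females by re-simulating their BDR as noise
        females = cohort["sex"] == "Female"
        rng = np.random.default_rng(seed)
        cohort.loc[females, "bdr"] = 0.1 + 0.07 * rng.standard_normal(int(females.sum()))
        res, _ = stratified_screen(cohort, proc, "sex", covariates=("race",))
        p = res.set_index("stratum")["p"]
        wins += p["Male"] < p["Female"]
    assert wins >= 8


def test_metabolite_age_trend_planted_slope():
    cfg = b.SimConfig(n_subjects=200, n_features=1, frac_active=0.0,
                      lcms=CLEAN_LCMS, seed=14)
    cohort, fm, _ = b.simulate_cohort(cfg)
    proc, _ = b.preprocess(fm)
    z = proc.study_frame()
    age = cohort.set_index("sample_id")["age_years"].reindex(z.columns)
    rng = np.random.default_rng(0)
    z.loc["f_trend"] = 0.03 * age.to_numpy() + 1e-6 * rng.standard_normal(len(age))
    out = metabolite_age_trend(cohort, z, "baseline", feature_ids=["f_trend"])
    assert out["beta"].iloc[0] == pytest.approx(0.03, rel=1e-3)
    assert out["p"].iloc[0] < 1e-10


def test_metabolite_age_trend_bh_family_of_two():
    cfg = b.SimConfig(n_subjects=100, n_features=2, frac_active=0.0,
                      lcms=CLEAN_LCMS, seed=15)
    cohort, fm, _ = b.simulate_cohort(cfg)
    proc, _ = b.preprocess(fm)
    out = metabolite_age_trend(cohort, proc, "baseline")
    assert out["q"].to_numpy() == pytest.approx(bh_adjust(out["p"].to_numpy()))


def test_metabolite_age_trend_unknown_feature():
    cfg = b.SimConfig(n_subjects=40, n_features=1, frac_active=0.0,
                      lcms=CLEAN_LCMS, seed=16)
    cohort, fm, _ = b.simulate_cohort(cfg)
    proc, _ = b.preprocess(fm)
    with pytest.raises(KeyError):
        metabolite_age_trend(cohort, proc, "baseline", feature_ids=["nope"])


# ---------------------------------------------------------------------------
# QQ points
# ---------------------------------------------------------------------------

def test_qq_single_point():
    out = qq_points([0.5])
    assert out["expected_neglog10_p"].iloc[0] == pytest.approx(-np.log10(0.5))
    assert out["observed_neglog10_p"].iloc[0] == pytest.approx(-np.log10(0.5))


def test_qq_uniform_near_identity():
    rng = np.random.default_rng(17)
    out = qq_points(rng.random(1000))
    mid = len(out) // 2
    assert abs(out["observed_neglog10_p"].iloc[mid]
               - out["expected_neglog10_p"].iloc[mid]) < 0.1


def test_qq_zero_p_clamped(caplog):
    with caplog.at_level("WARNING"):
        out = qq_points([0.0, 0.5])
    assert np.isfinite(out["observed_neglog10_p"]).all()
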