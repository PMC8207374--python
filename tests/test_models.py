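import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from zoicomp import (FitError, GrowthModel, ScanConfig, SurvivalModel, aicc,
                     apply_fit_exclusions, basal_area, exclude_outliers,
                     grid_cells, growth_observations, growth_rate,
                     survival_observations)
from zoicomp.census import Census, PlotSpec, focal_subset
from zoicomp.models import ScanResults, compare_aicc, _bimodality
from tests.conftest import make_trees


def synth_growth(n=500, alpha=0.5, beta=-0.2, gamma=-0.1, sigma=0.2, seed=0):
    rng = np.random.default_rng(seed)
    d = pd.DataFrame({
        "ln_ba": rng.normal(4.0, 1.0, n),
        "ln_con": rng.normal(3.0, 1.2, n),
        "ln_het": rng.normal(5.0, 1.0, n)})
    d["ln_agr"] = (0.5 + alpha * d.ln_ba + beta * d.ln_con
                   + gamma * d.ln_het + rng.normal(0, sigma, n))
    return d


def test_growth_rate_arithmetic_and_floor():
    agr = growth_rate(basal_area(10.0), basal_area(20.0), 10.0)
    assert agr == pytest.approx((31.831 - 7.958) / 10.0, abs=5e-4)
    assert growth_rate(50.0, 50.0, 10.0) == 0.01           # floored
    assert np.isnan(growth_rate(50.0, 40.0, 10.0, nonpositive="drop"))
    with pytest.raises(ValueError):
        growth_rate(1.0, 2.0, 10.0, nonpositive="bogus")


def test_growth_observations_exclude_dead(toy_census):
    period = toy_census.plot.period(1)
    focal = toy_census.trees
    obs = growth_observations(toy_census, focal, period)
    assert set(obs["focal_id"]) == {"a1", "b1", "b2"}   # a2 died
    sobs = survival_observations(toy_census, focal, period)
    assert dict(zip(sobs["focal_id"], sobs["survived"])) == {
        "a1": 1, "a2": 0, "b1": 1, "b2": 1}


def test_exclude_outliers_drops_planted_point_and_is_idempotent():
    rng = np.random.default_rng(1)
    n = 80
    obs = pd.DataFrame({
        "focal_id": [f"t{i}" for i in range(n)],
        "ln_ba": rng.normal(4, 1, n)})
    obs["ln_agr"] = 0.5 * obs.ln_ba + rng.normal(0, 0.3, n)
    clean, dropped = exclude_outliers(obs)
    assert dropped == []
    bad = obs.copy()
    bad.loc[0, "ln_agr"] -= 10 * 0.3
    kept, dropped = exclude_outliers(bad)
    assert dropped == ["t0"]
    again, dropped2 = exclude_outliers(kept)
    assert dropped2 == [] and len(again) == len(kept)


def test_growth_model_recovers_generative_coefficients():
    d = synth_growth(seed=3)
    res = GrowthModel.from_dataframe(d).fit()
    for term, truth in (("ln_ba", 0.5), ("ln_con", -0.2), ("ln_het", -0.1)):
        assert abs(res.params[term] - truth) < 3 * res.bse[term]
    assert res.k == 5            # 4 mean parameters + error variance
    assert np.isfinite(res.aicc)
    assert 0.0 < res.pred_r2 <= 1.0
    # effect sizes follow t2/(t2+df) and live in [0, 1]
    for term in ("ln_ba", "ln_con", "ln_het"):
        t = res.tvalues[term]
        es = res.effect_size(term)
        assert es == pytest.approx(t**2 / (t**2 + res.df_resid))
        assert 0.0 <= es <= 1.0
    assert "AICc" in str(res.summary())


def test_press_predicted_r2_matches_leave_one_out():
    d = synth_growth(n=30, seed=5)
    res = GrowthModel.from_dataframe(d).fit()
    y = d["ln_agr"].to_numpy()
    X = sm.add_constant(d[["ln_ba", "ln_con", "ln_het"]].to_numpy())
    press = 0.0
    for i in range(len(d)):
        keep = np.arange(len(d)) != i
        fit = sm.OLS(y[keep], X[keep]).fit()
        press += (y[i] - fit.predict(X[i][None, :])[0]) ** 2
    assert res.press == pytest.approx(press, rel=1e-8)
    assert res.pred_r2 == pytest.approx(1 - press / np.sum((y - y.mean())**2))


def test_collinear_design_raises():
    d = synth_growth(n=50, seed=7)
    d["ln_het"] = 2.0 * d["ln_con"]
    with pytest.raises(FitError) as err:
        GrowthModel.from_dataframe(d)
    assert err.value.reason == "collinear"


def test_survival_model_recovery_and_pseudo_r2():
    rng = np.random.default_rng(11)
    n = 500
    d = pd.DataFrame({"ln_ba": rng.normal(4, 1, n),
                      "ln_con": rng.normal(3, 1.2, n),
                      "ln_het": rng.normal(5, 1, n)})
    from scipy.special import expit
    p = expit(3.0 + 0.2 * d.ln_ba - 0.5 * d.ln_con - 0.25 * d.ln_het)
    d["survived"] = (rng.random(n) < p).astype(int)
    res = SurvivalModel.from_dataframe(d).fit()
    assert abs(res.params["ln_con"] + 0.5) < 3 * res.bse["ln_con"]
    assert res.r_l2 > 0
    assert res.r_l2_adj < res.r_l2
    assert res.effect_size("ln_con") == pytest.approx(res.params["ln_con"])
    # odds conversion: beta = ln 2 doubles the odds (+100%)
    res.params["ln_con"] = np.log(2.0)
    assert res.odds_percent("ln_con") == pytest.approx(100.0)


def test_survival_null_model_r_l2_zero():
    rng = np.random.default_rng(2)
    d = pd.DataFrame({"survived": rng.integers(0, 2, 200)})
    res = SurvivalModel.from_dataframe(d, terms=()).fit()
    assert res.r_l2 == pytest.approx(0.0, abs=1e-8)


def test_survival_separation_is_unstable():
    d = pd.DataFrame({"ln_con": np.linspace(-2, 2, 40)})
    d["survived"] = (d.ln_con > 0).astype(int)
    with pytest.raises(FitError) as err:
        SurvivalModel.from_dataframe(d, terms=("ln_con",)).fit()
    assert err.value.reason == "unstable"
    with pytest.raises(FitError):
        SurvivalModel.from_dataframe(
            pd.DataFrame({"survived": [1, 1, 1], "ln_con": [1., 2., 3.]}),
            terms=("ln_con",))


def test_fit_exclusion_rule_counts():
    con = np.array([1.0] * 4 + [0.0] * 96)
    het = np.zeros(100)
    assert apply_fit_exclusions(con, het) == "few_con"
    con5 = np.array([1.0] * 5 + [0.0] * 95)
    het5 = np.concatenate([np.zeros(5), np.ones(95)])
    assert apply_fit_exclusions(con5, het5) is None
    het4 = np.concatenate([np.zeros(4), np.ones(96)])
    assert apply_fit_exclusions(con5, het4) == "few_zero_het"
    # survival models are never excluded this way
    assert apply_fit_exclusions(con, het4, response="survival") is None
    # brute-force equivalence on random data
    rng = np.random.default_rng(0)
    for _ in range(20):
        c = rng.random(50) * (rng.random(50) < 0.3)
        h = rng.random(50) * (rng.random(50) < 0.8)
        reason = apply_fit_exclusions(c, h)
        expected = ("few_con" if (c > 0).sum() < 5 else
                    "few_zero_het" if (h == 0).sum() < 5 else None)
        assert reason == expected


def test_grid_cardinalities():
    assert len(grid_cells()) == 19_600
    assert len(grid_cells(spatial=False)) == 400
    assert len(grid_cells(radii=(2, 4, 6, 8, 10), dd_levels=(0.0, 0.4))) == 100
    assert len(grid_cells(form="ba")) == 1
    assert len(grid_cells(spatial=False, form="ba+all")) == 20


def scan_results_from(rows, response="growth"):
    df = pd.DataFrame(rows)
    if "excluded_reason" not in df:
        df["excluded_reason"] = None
    return ScanResults("sp", 1, response, ScanConfig(), df, pd.DataFrame())


def test_average_band_examples():
    one = scan_results_from([
        dict(r_con=10, r_het=8, dd_con=0.2, dd_het=0.0, aicc=100.0,
             beta_con=-0.15, beta_het=-0.05, se_con=0.01, se_het=0.01)])
    g = one.average_band("con")
    assert g.coefficient == -0.15 and g.n_models == 1 and g.radius_range == 0.0
    two = scan_results_from([
        dict(r_con=8, r_het=8, dd_con=0.0, dd_het=0.0, aicc=100.0,
             beta_con=-0.1, se_con=0.01),
        dict(r_con=12, r_het=8, dd_con=0.4, dd_het=0.0, aicc=101.5,
             beta_con=-0.3, se_con=0.01),
        dict(r_con=20, r_het=8, dd_con=1.2, dd_het=0.0, aicc=104.0,
             beta_con=5.0, se_con=0.01)])          # outside the band
    g = two.average_band("con")
    assert g.coefficient == pytest.approx(-0.2)
    assert g.n_models == 2
    assert g.mean_radius == pytest.approx(10.0)
    assert g.radius_range == pytest.approx(4.0)
    assert g.mean_dd == pytest.approx(0.2)


def test_average_band_matches_brute_force_filter():
    rng = np.random.default_rng(8)
    rows = [dict(r_con=r, r_het=8, dd_con=0.0, dd_het=0.0,
                 aicc=float(rng.uniform(50, 58)),
                 beta_con=float(rng.normal(-0.2, 0.05)), se_con=0.01)
            for r in range(1, 21)]
    sr = scan_results_from(rows)
    g = sr.average_band("con")
    df = pd.DataFrame(rows)
    band = df[df.aicc - df.aicc.min() <= 2.0]
    assert g.n_models == len(band)
    assert g.coefficient == pytest.approx(band.beta_con.mean())


def test_survival_band_drops_huge_se():
    sr = scan_results_from([
        dict(r_con=8, r_het=8, dd_con=0.0, dd_het=0.0, aicc=10.0,
             beta_con=-0.4, se_con=0.2),
        dict(r_con=10, r_het=8, dd_con=0.0, dd_het=0.0, aicc=10.5,
             beta_con=-90.0, se_con=350.0)], response="survival")
    g = sr.average_band("con")
    assert g.n_models == 1 and g.coefficient == -0.4


def test_scan_compare_to_reference_and_plot():
    sr = scan_results_from([
        dict(r_con=8, r_het=8, dd_con=0.0, dd_het=0.0, aicc=92.0,
             beta_con=-0.2, se_con=0.01)])
    assert sr.compare_to_reference(100.0) == "much_better"
    assert sr.compare_to_reference(93.0) == "indistinguishable"
    ref = scan_results_from([dict(r_con=8, r_het=8, dd_con=0.0, dd_het=0.0,
                                  aicc=80.0, beta_con=0.0, se_con=0.01)])
    assert sr.compare_to_reference(ref) == "much_worse"
    ax = sr.plot_coefficient_hist("con")
    assert ax.get_xlabel().startswith("CON")


def test_compare_aicc_thresholds():
    assert compare_aicc(-8.0) == "much_better"
    assert compare_aicc(-7.0) == "much_better"
    assert compare_aicc(0.0) == "indistinguishable"
    assert compare_aicc(6.9) == "indistinguishable"
    assert compare_aicc(7.1) == "much_worse"


def test_aicc_formula_edge_cases():
    assert aicc(-10.0, 30, 4) == pytest.approx(20 + 8 + 40 / 25)
    assert aicc(-10.0, 5, 4) == np.inf


def test_bimodality_diagnostic():
    rng = np.random.default_rng(0)
    uni = rng.normal(-0.2, 0.02, 200)
    assert _bimodality(uni, uni.mean())[0] is False
    split = np.concatenate([rng.normal(-0.3, 0.02, 100),
                            rng.normal(0.3, 0.02, 100)])
    flag, kind = _bimodality(split, split.mean())
    assert flag and kind == "sign_split"
    # same-sign modes: bimodal only when separation >= 2 |mean|, which
    # requires unbalanced clusters
    sep = np.concatenate([rng.normal(0.05, 0.005, 180),
                          rng.normal(0.9, 0.005, 20)])
    flag, kind = _bimodality(sep, sep.mean())
    assert flag and kind == "peak_separation"


def test_nonspatial_scan_on_small_forest(small_forest):
    census, spec = small_forest
    from zoicomp import NeighborhoodScan
    cfg = ScanConfig(spatial=False, decay="linear", radii=(5, 10, 15),
                     position_mode="stem")
    sr = NeighborhoodScan(census, "sp01", 1, "growth", cfg).fit(seed=0)
    assert len(sr.results) == 9
    assert {"beta_con", "beta_het", "aicc"} <= set(sr.results.columns)
    assert sr.best["aicc"] == sr.fitted["aicc"].min()
    assert "Neighborhood scan" in sr.summary()


def test_reference_form_scans(small_forest):
    """The ba-only and ba+ALL reference forms fit and compare by AICc."""
    census, _ = small_forest
    from zoicomp import NeighborhoodScan
    ref_cfg = ScanConfig(spatial=False, form="ba+all", radii=(5, 10, 15))
    ref = NeighborhoodScan(census, "sp01", 1, "growth", ref_cfg).fit(seed=0)
    assert len(ref.results) == 3
    assert "beta_all" in ref.results.columns
    g = ref.average_band("all")
    assert np.isfinite(g.coefficient) and g.n_models >= 1
    ba_cfg = ScanConfig(spatial=False, form="ba", radii=(5,))
    ba_only = NeighborhoodScan(census, "sp01", 1, "growth", ba_cfg).fit(seed=0)
    assert len(ba_only.results) == 1
    two = ScanConfig(spatial=False, radii=(5, 10, 15))
    full = NeighborhoodScan(census, "sp01", 1, "growth", two).fit(seed=0)
    assert full.compare_to_reference(ref) in (
        "much_better", "much_worse", "indistinguishable")
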