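"""Variance decomposition, ICCs, Rubin pooling and reshaping."""

import warnings

import numpy as np
import pandas as pd
import pytest

from citymort.ages import CAUSE_GROUPS
from citymort.inference import (
    ModelSpec,
    decompose_variance,
    icc_country,
    le_association,
    pool_rubin,
    random_intercept_gls,
    reshape_for_cause_model,
)


def draw_panel(rng, tau_country, tau_city, sigma2, n_country, n_city, n_draw):
    rows = []
    for k in range(n_country):
        ck = rng.normal(0, np.sqrt(tau_country))
        for j in range(n_city):
            cj = ck + rng.normal(0, np.sqrt(tau_city))
            vals = cj + rng.normal(0, np.sqrt(sigma2), n_draw)
            rows.append(pd.DataFrame(dict(
                iteration=np.arange(n_draw), city_id=f"{k}-{j}",
                country_id=f"K{k}", life_expectancy=vals, weight=1.0,
            )))
    return pd.concat(rows, ignore_index=True)


class TestDecomposeVariance:
    def test_identical_values_give_zero_components(self):
        panel = draw_panel(np.random.default_rng(0), 0, 0, 0, 3, 4, 10)
        panel["life_expectancy"] = 70.0
        vc = decompose_variance(panel)
        assert vc.total == pytest.approx(0.0, abs=1e-12)

    def test_country_differences_only(self):
        rows = []
        for k, level in enumerate([60.0, 70.0, 80.0]):
            for j in range(4):
                rows.append(pd.DataFrame(dict(
                    iteration=np.arange(5), city_id=f"{k}-{j}",
                    country_id=f"K{k}", life_expectancy=level, weight=1.0,
                )))
        vc = decompose_variance(pd.concat(rows, ignore_index=True))
        assert vc.sigma2_draw == pytest.approx(0.0, abs=1e-12)
        assert vc.tau_city == pytest.approx(0.0, abs=1e-12)
        assert vc.tau_country > 0
        assert vc.proportions["country"] == pytest.approx(1.0)

    def test_simulation_recovery(self):
        # with 9 countries a single replicate's between-country variance
        # carries ~50% sampling error and the share is a ratio (Jensen
        # bias), so recovery is judged on components averaged over
        # replicates before forming proportions
        rng = np.random.default_rng(3)
        comps = []
        for _ in range(20):
            panel = draw_panel(rng, 3.0, 1.0, 0.5, 9, 40, 100)
            vc = decompose_variance(panel)
            comps.append([vc.tau_country, vc.tau_city, vc.sigma2_draw])
        mean = np.mean(comps, axis=0)
        props = mean / mean.sum()
        truth = np.array([3.0, 1.0, 0.5]) / 4.5
        np.testing.assert_allclose(props, truth, atol=0.05)

    def test_proportions_sum_to_one(self):
        panel = draw_panel(np.random.default_rng(4), 2.0, 1.0, 1.0, 5, 6, 20)
        assert sum(decompose_variance(panel).proportions.values()) == pytest.approx(1.0)

    def test_single_country_flagged(self):
        panel = draw_panel(np.random.default_rng(5), 0.0, 1.0, 0.5, 1, 8, 20)
        vc = decompose_variance(panel)
        assert vc.single_country and vc.tau_country == 0.0

    def test_unbalanced_draws_rejected(self):
        panel = draw_panel(np.random.default_rng(6), 1, 1, 1, 2, 2, 10)
        with pytest.raises(ValueError):
            decompose_variance(panel.iloc[:-3])

    def test_agrees_with_reml_cross_check(self):
        # independent oracle: restricted-likelihood fit of the same
        # three-level model via statsmodels variance components
        from statsmodels.regression.mixed_linear_model import MixedLM

        panel = draw_panel(np.random.default_rng(7), 2.0, 1.0, 0.5, 6, 12, 30)
        vc = decompose_variance(panel)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = MixedLM.from_formula(
                "life_expectancy ~ 1", groups="country_id",
                re_formula="1", vc_formula={"city": "0 + C(city_id)"},
                data=panel,
            ).fit(reml=True)
        tau_country = float(fit.cov_re.iloc[0, 0])
        tau_city = float(fit.vcomp[0])
        sigma2 = float(fit.scale)
        assert vc.tau_country == pytest.approx(tau_country, rel=0.15, abs=0.1)
        assert vc.tau_city == pytest.approx(tau_city, rel=0.15, abs=0.1)
        assert vc.sigma2_draw == pytest.approx(sigma2, rel=0.05)


class TestICC:
    def test_identical_countries_zero(self):
        df = pd.DataFrame({"country_id": ["A"] * 5 + ["B"] * 5,
                           "value": list(range(5)) * 2})
        assert icc_country(df) == pytest.approx(0.0, abs=0.05)

    def test_no_within_country_variance_is_one(self):
        df = pd.DataFrame({"country_id": ["A"] * 5 + ["B"] * 5,
                           "value": [1.0] * 5 + [2.0] * 5})
        assert icc_country(df) == pytest.approx(1.0)

    def test_simulation_recovery(self):
        rng = np.random.default_rng(8)
        rows = []
        for k in range(40):
            ck = rng.normal(0, 1.0)
            for j in range(20):
                rows.append(dict(country_id=f"K{k}", value=ck + rng.normal()))
        assert icc_country(pd.DataFrame(rows)) == pytest.approx(0.5, abs=0.05)


class TestRubin:
    def test_degenerate_case_returns_inputs_exactly(self):
        pc = pool_rubin(np.full(50, 1.7), np.full(50, 0.09))
        assert pc.estimate == 1.7
        assert pc.within == pytest.approx(0.09)
        assert pc.between == 0.0
        assert pc.total_variance == pytest.approx(0.09)

    def test_between_variance_inflates_total(self):
        rng = np.random.default_rng(9)
        pc = pool_rubin(rng.normal(1.0, 0.5, 100), np.full(100, 0.01))
        assert pc.total_variance > pc.within

    def test_large_m_factor_approaches_w_plus_b(self):
        q = np.array([0.0, 2.0] * 500)
        pc = pool_rubin(q, np.full(1000, 0.1))
        assert pc.total_variance == pytest.approx(pc.within + pc.between, rel=0.01)

    def test_ci_symmetric_about_estimate(self):
        pc = pool_rubin(np.array([1.0, 1.2, 0.8]), np.array([0.1, 0.1, 0.1]))
        lo, hi = pc.ci95
        assert (lo + hi) / 2 == pytest.approx(pc.estimate)


def synthetic_association_panel(rng, effect=0.5, n_country=6, n_city=8, m=50):
    cities = pd.DataFrame([
        dict(city_id=f"{k}-{j}", country_id=f"K{k}", sei=rng.normal())
        for k in range(n_country) for j in range(n_city)
    ])
    country_effect = {f"K{k}": rng.normal(0, 0.7) for k in range(n_country)}
    frames = []
    for it in range(m):
        le = (70 + effect * cities.sei
              + cities.country_id.map(country_effect)
              + rng.normal(0, 0.4, len(cities)))
        frames.append(pd.DataFrame(dict(
            iteration=it, city_id=cities.city_id,
            country_id=cities.country_id, life_expectancy=le)))
    return pd.concat(frames, ignore_index=True), cities


class TestAssociation:
    def test_recovers_known_effect_within_ci(self):
        rng = np.random.default_rng(10)
        panel, cities = synthetic_association_panel(rng, effect=0.5)
        pc = le_association(panel, cities[["city_id", "sei"]],
                            ModelSpec(predictors=["sei"]))[0]
        lo, hi = pc.ci95
        assert lo <= 0.5 <= hi
        assert pc.estimate == pytest.approx(0.5, abs=0.15)

    def test_gls_matches_reml_backend(self):
        rng = np.random.default_rng(11)
        panel, cities = synthetic_association_panel(rng, effect=0.3, m=10)
        a = le_association(panel, cities[["city_id", "sei"]],
                           ModelSpec(predictors=["sei"]), backend="mom")[0]
        b = le_association(panel, cities[["city_id", "sei"]],
                           ModelSpec(predictors=["sei"]), backend="reml")[0]
        assert a.estimate == pytest.approx(b.estimate, rel=0.02)
        assert a.within == pytest.approx(b.within, rel=0.15)

    def test_null_effect_rejection_rate_near_nominal(self):
        # with no true effect the pooled 95% CI should exclude zero in
        # roughly 5% of repeated simulations
        rng = np.random.default_rng(12)
        rejected = 0
        n_sim = 60
        for _ in range(n_sim):
            panel, cities = synthetic_association_panel(rng, effect=0.0, m=8)
            pc = le_association(panel, cities[["city_id", "sei"]],
                                ModelSpec(predictors=["sei"]))[0]
            lo, hi = pc.ci95
            rejected += not (lo <= 0.0 <= hi)
        assert rejected / n_sim < 0.15

    def test_gls_estimator_matches_ols_when_one_group(self):
        rng = np.random.default_rng(13)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        y = X @ np.array([1.0, 2.0]) + rng.normal(0, 0.3, 30)
        beta, cov = random_intercept_gls(y, X, np.zeros(30, dtype=int))
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(beta, ols, rtol=1e-8)


class TestReshape:
    def _inputs(self):
        deaths = pd.DataFrame([
            dict(country_id="K1", city_id=c, cause_group=g, deaths=10 * (i + 1))
            for c in ("a", "b", "c")
            for i, g in enumerate(CAUSE_GROUPS)
        ])
        predictors = pd.DataFrame(dict(city_id=["a", "b", "c"],
                                       sei=[0.1, -0.2, 0.5]))
        pop = pd.DataFrame(dict(city_id=["a", "b", "c"],
                                population=[1e5, 2e5, 3e5]))
        cov = pd.DataFrame(dict(city_id=["a", "b", "c"], phi=[0.8, 0.9, 1.0]))
        return deaths, predictors, pop, cov

    def test_cardinality_and_offset(self):
        deaths, predictors, pop, cov = self._inputs()
        out = reshape_for_cause_model(deaths, predictors, pop, coverage=cov,
                                      exposure_cols=("sei",))
        assert len(out) == 15  # 5 causes x 3 cities
        a_rows = out[out.city_id == "a"]
        assert np.allclose(a_rows["offset"], np.log(1e5 * 0.8))

    def test_reference_cause_has_zero_indicators(self):
        deaths, predictors, pop, cov = self._inputs()
        out = reshape_for_cause_model(deaths, predictors, pop,
                                      exposure_cols=("sei",))
        ref = out[out.cause_group == "CVD_NCD"]
        ind_cols = [c for c in out.columns if c.startswith("cause_")
                    and c != "cause_group"]
        inter_cols = [c for c in out.columns if "_x_" in c]
        assert (ref[ind_cols].to_numpy() == 0).all()
        assert (ref[inter_cols].to_numpy() == 0).all()
        other = out[out.cause_group == "CMNN"]
        assert (other["cause_CMNN"] == 1).all()
        np.testing.assert_allclose(other["sei_x_CMNN"], other["sei"])
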