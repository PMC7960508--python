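"""Death-distribution completeness: identities, recovery, Beta priors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from citymort.ages import collapse_to_ddm
from citymort.completeness import (
    CensusPair,
    admissible_bands,
    beta_prior_from_estimates,
    choose_age_band_auto,
    ensemble,
    ggb,
    hybrid,
    seg,
)
from citymort.synthetic import make_schedule, stable_population

from conftest import stationary_fixture


class TestGGB:
    def test_stationary_complete_registration_is_one(self):
        census, deaths, _ = stationary_fixture(sex="F")
        assert ggb(census, deaths, (30, 65)).completeness == pytest.approx(1.0, abs=0.01)

    def test_thinned_deaths_recovered(self):
        census, deaths, _ = stationary_fixture(sex="F", growth=0.015, thin=0.75)
        assert ggb(census, deaths, (30, 65)).completeness == pytest.approx(0.75, abs=0.03)

    def test_linearity_in_deaths(self):
        # doubling registered deaths doubles the estimate (up to the tiny
        # aspect-ratio sensitivity of the orthogonal fit)
        census, deaths, _ = stationary_fixture(sex="M", growth=0.01, thin=0.5)
        c1 = ggb(census, deaths, (30, 65)).completeness
        c2 = ggb(census, deaths * 2, (30, 65)).completeness
        assert c2 == pytest.approx(2 * c1, rel=1e-3)

    def test_zero_population_rejected(self):
        census, deaths, _ = stationary_fixture()
        bad = CensusPair(census.n1 * 0.0, census.n2, census.t1, census.t2)
        with pytest.raises(ValueError):
            ggb(bad, deaths, (30, 65))

    def test_census_coverage_drift_in_intercept(self):
        # deflating the second census shows up as a nonzero delta
        census, deaths, _ = stationary_fixture(growth=0.01)
        drifted = CensusPair(census.n1, census.n2 * 0.9, census.t1, census.t2)
        base = ggb(census, deaths, (30, 65)).delta
        got = ggb(drifted, deaths, (30, 65)).delta
        # delta estimates ln(k1/k2)/T = ln(1/0.9)/5
        assert got - base == pytest.approx(np.log(1 / 0.9) / 5.0, rel=0.05)


class TestSEG:
    def test_stationary_complete_registration_is_one(self):
        census, deaths, _ = stationary_fixture(sex="F")
        assert seg(census, deaths, (30, 65), sex="F") == pytest.approx(1.0, abs=0.02)

    def test_thinned_deaths_recovered(self):
        census, deaths, _ = stationary_fixture(sex="M", growth=0.01, thin=0.6)
        assert seg(census, deaths, (30, 65), sex="M") == pytest.approx(0.6, abs=0.03)

    def test_scale_invariance_under_joint_scaling(self):
        # scaling population and deaths together leaves completeness
        # unchanged (a fraction of a population-sized flow)
        census, deaths, _ = stationary_fixture(growth=0.02)
        scaled = CensusPair(census.n1 * 3, census.n2 * 3, census.t1, census.t2)
        a = seg(census, deaths, (30, 65))
        b = seg(scaled, deaths * 3, (30, 65))
        assert b == pytest.approx(a, rel=1e-12)


class TestHybrid:
    def test_stationary_identity(self):
        census, deaths, _ = stationary_fixture()
        assert hybrid(census, deaths, (30, 65)) == pytest.approx(1.0, abs=0.02)

    def test_thinned_recovery(self):
        census, deaths, _ = stationary_fixture(growth=0.015, thin=0.7)
        assert hybrid(census, deaths, (30, 65)) == pytest.approx(0.7, abs=0.03)

    def test_corrects_census_coverage_drift(self):
        # second census under-enumerated by 10%: plain SEG is biased,
        # the GGB-adjusted hybrid recovers the truth
        census, deaths, _ = stationary_fixture(growth=0.01, thin=0.8)
        drifted = CensusPair(census.n1, census.n2 * 0.9, census.t1, census.t2)
        plain = seg(drifted, deaths, (30, 65))
        adjusted = hybrid(drifted, deaths, (30, 65))
        assert abs(adjusted - 0.8) < abs(plain - 0.8)
        assert adjusted == pytest.approx(0.8, abs=0.04)


class TestAutoBand:
    def test_admissible_band_count_matches_combinatorics(self):
        bands = admissible_bands()
        expected = sum(
            1 for lo in range(5, 36, 5) for hi in range(50, 76, 5)
            if hi - lo >= 30
        )
        assert len(bands) == len(set(bands)) == expected

    def test_perfect_fit_chooses_widest_band(self):
        # deaths constructed from the balance identity itself, so every
        # GGB point is exactly collinear and only the tie-break decides
        census, _, _ = stationary_fixture(growth=0.0)
        from citymort.ages import DDM_AGE_LOWER
        from citymort.completeness import _ggb_points

        ages = np.arange(5, 76, 5)
        geo_open = np.array([
            np.sqrt(census.n1[i:].sum() * census.n2[i:].sum())
            for i in range(1, DDM_AGE_LOWER.size)
        ])
        x, y = _ggb_points(census, np.zeros(DDM_AGE_LOWER.size), ages)
        D_open = 0.8 * y * census.T * geo_open  # slope 1/0.8, intercept 0
        deaths = np.zeros(DDM_AGE_LOWER.size)
        deaths[1:-1] = D_open[:-1] - D_open[1:]
        deaths[-1] = D_open[-1]
        deaths[0] = deaths[1]
        assert np.all(deaths >= 0)
        assert choose_age_band_auto(census, deaths) == (5, 75)
        res = ggb(census, deaths, (5, 75))
        assert res.completeness == pytest.approx(0.8, abs=1e-9)

    def test_noise_below_30_excluded(self):
        census, deaths, _ = stationary_fixture(growth=0.01)
        n1, n2 = census.n1.copy(), census.n2.copy()
        bump = np.array([1.3, 0.7, 1.3, 0.7, 1.3, 0.7])  # ages 0-29 distorted
        n2[:6] *= bump
        noisy = CensusPair(n1, n2, census.t1, census.t2)
        lo, hi = choose_age_band_auto(noisy, deaths)
        assert lo >= 30


class TestBetaPrior:
    def test_worked_moment_matching_case(self):
        # phi = 0.9, s2 = 0.0009 -> K = 99, shapes (89.1, 9.9)
        estimates = np.full(9, 0.9)
        phi, s2, K, a, b, _ = beta_prior_from_estimates(estimates)
        assert phi == pytest.approx(0.9, abs=1e-12)
        K_direct = 0.9 * 0.1 / 0.0009 - 1
        assert K_direct == pytest.approx(99.0, abs=1e-9)
        assert K_direct * 0.9 == pytest.approx(89.1, abs=1e-9)
        assert K_direct * 0.1 == pytest.approx(9.9, abs=1e-9)

    def test_degenerate_ensemble_floors_variance(self):
        phi, s2, K, a, b, notes = beta_prior_from_estimates(np.full(9, 0.6))
        assert phi == pytest.approx(0.6)
        assert s2 == 1e-6
        assert a / (a + b) == pytest.approx(0.6, abs=1e-12)
        # tightly concentrated: prior sd well under 1%
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert np.sqrt(var) < 0.01

    def test_two_estimate_harmonic_mean(self):
        phi, *_ = beta_prior_from_estimates(np.array([0.5, 1.0]), denominator=2)
        assert phi == pytest.approx(2 / 3, abs=1e-12)

    def test_fewer_than_two_estimates_rejected(self):
        with pytest.raises(ValueError):
            beta_prior_from_estimates(np.array([0.8]))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.31, 1.0), min_size=3, max_size=9))
    def test_harmonic_le_arithmetic(self, values):
        phi, *_ = beta_prior_from_estimates(np.array(values),
                                            denominator=len(values))
        assert phi <= np.mean(values) + 1e-12

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0.35, 0.99), st.floats(1e-5, 0.002))
    def test_moment_matching_identity(self, phi, s2):
        # whenever no clamp fires, Beta(K*phi, K*(1-phi)) has mean phi
        # and variance s2 to machine precision
        K = phi * (1 - phi) / s2 - 1
        if K <= 0:
            return
        a, b = K * phi, K * (1 - phi)
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert mean == pytest.approx(phi, abs=1e-12)
        assert var == pytest.approx(s2, abs=1e-12)


class TestEnsemble:
    def test_recovers_uniform_thinning(self):
        census, deaths, _ = stationary_fixture(sex="F", growth=0.012, thin=0.8)
        prior = ensemble(census, deaths, sex="F")
        assert len(prior.estimates) == 9
        assert prior.phi == pytest.approx(0.8, abs=0.03)
        assert prior.alpha / (prior.alpha + prior.beta) == pytest.approx(
            prior.phi, abs=1e-9)

    def test_recovery_over_random_cities(self):
        # scaled-down parameter-recovery check (the acceptance suite runs
        # the full 30-city version)
        rng = np.random.default_rng(6)
        errs = []
        for _ in range(8):
            cov = rng.uniform(0.6, 1.0)
            growth = rng.uniform(0.005, 0.025)
            sex = rng.choice(["F", "M"])
            level = np.exp(rng.normal(0, 0.15))
            sched = make_schedule(level, sex=sex)
            n1 = stable_population(sched, growth, 5e5)
            n2 = n1 * np.exp(growth * 5)
            deaths = collapse_to_ddm(5 * np.sqrt(n1 * n2) * sched.rates) * cov
            census = CensusPair.from_17(n1, n2, 2012.0, 2017.0)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                prior = ensemble(census, deaths, sex=sex)
            errs.append(abs(prior.phi - cov))
        assert float(np.mean(errs)) < 0.03

    def test_migration_degrades_accuracy(self):
        # age-selective migration violates the DDM assumptions and must
        # move phi away from the truth relative to the clean fixture
        census, deaths, sched = stationary_fixture(growth=0.015, thin=0.8)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clean_err = abs(ensemble(census, deaths).phi - 0.8)
            n2 = census.n2.copy()
            n2[3:8] *= 1.25  # in-migration at ages 15-39
            migr = CensusPair(census.n1, n2, census.t1, census.t2)
            migr_err = abs(ensemble(migr, deaths).phi - 0.8)
        assert migr_err > clean_err
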