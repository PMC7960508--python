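"""Count conservation and stratum logic of the preprocessing chain."""

import numpy as np
import pandas as pd
import pytest

from citymort.ages import AGE_GROUPS, CAUSE_GROUPS, DISEASE_CAUSES, INJURY_CAUSES
from citymort.preprocess import (
    assign_cause_groups,
    impute_age,
    impute_sex,
    preprocess,
    redistribute_ill_defined,
    summarize_ill_defined,
)

COLS = ["country_id", "city_id", "year", "sex", "age_group", "cause_group", "deaths"]


def rows(*tuples):
    return pd.DataFrame(list(tuples), columns=COLS)


def base_row(sex="F", age="40-44", cause="CVD_NCD", deaths=10, year=2012,
             country="C1", city="C1-01"):
    return (country, city, year, sex, age, cause, deaths)


class TestImputeSex:
    def test_no_missing_is_identity(self):
        t = rows(base_row(), base_row(sex="M"))
        out = impute_sex(t, seed=1)
        pd.testing.assert_frame_equal(
            out.sort_values(COLS[:-1]).reset_index(drop=True),
            t.sort_values(COLS[:-1]).reset_index(drop=True),
        )

    def test_all_male_stratum_assigns_male(self):
        t = rows(base_row(sex="M", deaths=50), base_row(sex="missing", deaths=7))
        out = impute_sex(t, seed=1)
        assert out[out.sex == "M"].deaths.sum() == 57
        assert (out.sex != "F").all()

    def test_binomial_oracle_half_split(self):
        # p = 0.5 stratum, 1000 missing: males within 4*sqrt(250) of 500
        t = rows(base_row(sex="M", deaths=400), base_row(sex="F", deaths=400),
                 base_row(sex="missing", deaths=1000))
        for seed in (1, 2, 3, 4, 5):
            out = impute_sex(t, seed=seed)
            males = out[out.sex == "M"].deaths.sum() - 400
            assert abs(males - 500) <= 63

    def test_fallback_ladder_when_stratum_empty(self):
        # missing row's (age, cause, year) stratum has no observed deaths;
        # the observed data live in another year -> collapsed-year stratum
        t = rows(base_row(sex="M", deaths=30, year=2013),
                 base_row(sex="missing", deaths=5, year=2012))
        out = impute_sex(t, seed=1)
        assert out[out.sex == "M"].deaths.sum() == 35

    def test_expectation_mode_deterministic(self):
        t = rows(base_row(sex="M", deaths=30), base_row(sex="F", deaths=10),
                 base_row(sex="missing", deaths=8))
        out = impute_sex(t, mode="expect")
        assert out[out.sex == "M"].deaths.sum() == pytest.approx(36.0)
        assert out[out.sex == "F"].deaths.sum() == pytest.approx(12.0)

    def test_seed_required_in_draw_mode(self):
        t = rows(base_row(sex="missing"), base_row(sex="M"))
        with pytest.raises(ValueError):
            impute_sex(t, seed=None)


class TestImputeAge:
    def test_single_observed_group_takes_all(self):
        t = rows(base_row(age="60-64", deaths=20), base_row(age="missing", deaths=9))
        out = impute_age(t, seed=1)
        assert out[out.age_group == "60-64"].deaths.sum() == 29

    def test_no_missing_identity(self):
        t = rows(base_row(), base_row(age="25-29"))
        out = impute_age(t, seed=1)
        assert out.deaths.sum() == t.deaths.sum()
        assert set(out.age_group) == {"40-44", "25-29"}

    def test_multinomial_oracle_uniform(self):
        obs = [base_row(age=a, deaths=100) for a in AGE_GROUPS]
        t = rows(*obs, base_row(age="missing", deaths=1700))
        out = impute_age(t, seed=3)
        got = out.groupby("age_group")["deaths"].sum() - 100
        sd = np.sqrt(1700 * (1 / 17) * (16 / 17))
        assert np.all(np.abs(got.to_numpy() - 100) <= 4 * sd)
        assert out.deaths.sum() == t.deaths.sum()


class TestRedistribution:
    def test_no_ill_defined_identity(self):
        t = rows(base_row(), base_row(cause="CANCER"))
        out = redistribute_ill_defined(t, seed=1)
        assert out.deaths.sum() == t.deaths.sum()

    def test_single_observed_disease_takes_all(self):
        t = rows(base_row(cause="CVD_NCD", deaths=100),
                 base_row(cause="ILLDEF_DISEASE", deaths=10))
        out = redistribute_ill_defined(t, seed=1)
        assert out[out.cause_group == "CVD_NCD"].deaths.sum() == 110

    def test_multinomial_oracle_disease_split(self):
        t = rows(base_row(cause="CMNN", deaths=2000),
                 base_row(cause="CANCER", deaths=3000),
                 base_row(cause="CVD_NCD", deaths=5000),
                 base_row(cause="ILLDEF_DISEASE", deaths=10000))
        out = redistribute_ill_defined(t, seed=2)
        for cause, p in (("CMNN", 0.2), ("CANCER", 0.3), ("CVD_NCD", 0.5)):
            got = out[out.cause_group == cause].deaths.sum() - 10000 * p
            sd = np.sqrt(10000 * p * (1 - p))
            assert abs(got - 10000 * p) <= 4 * sd

    def test_family_boundary_never_crossed(self):
        t = rows(base_row(cause="CMNN", deaths=10),
                 base_row(cause="UNINTENTIONAL", deaths=70),
                 base_row(cause="VIOLENT", deaths=30),
                 base_row(cause="ILLDEF_DISEASE", deaths=55),
                 base_row(cause="ILLDEF_INJURY", deaths=44))
        out = redistribute_ill_defined(t, seed=5)
        disease = out[out.cause_group.isin(DISEASE_CAUSES)].deaths.sum()
        injury = out[out.cause_group.isin(INJURY_CAUSES)].deaths.sum()
        assert disease == 10 + 55
        assert injury == 100 + 44

    def test_missing_values_rejected(self):
        t = rows(base_row(sex="missing"), base_row(cause="ILLDEF_DISEASE"))
        with pytest.raises(ValueError):
            redistribute_ill_defined(t, seed=1)

    def test_uniform_fallback_warns(self):
        t = rows(base_row(cause="ILLDEF_INJURY", deaths=9),
                 base_row(cause="CMNN", deaths=5))
        with pytest.warns(UserWarning):
            out = redistribute_ill_defined(t, seed=1)
        assert out[out.cause_group.isin(INJURY_CAUSES)].deaths.sum() == 9


def random_tables(n_tables, rng):
    """Batch of randomized small tables as disjoint country blocks;
    strata never span countries, so one frame is n_tables tables."""
    frames = []
    causes = list(CAUSE_GROUPS) + ["ILLDEF_DISEASE", "ILLDEF_INJURY"]
    for i in range(n_tables):
        n_rows = rng.integers(6, 14)
        frames.append(pd.DataFrame({
            "country_id": f"T{i}",
            "city_id": f"T{i}-1",
            "year": rng.integers(2012, 2014, n_rows),
            "sex": rng.choice(["F", "M", "missing"], n_rows, p=[0.45, 0.45, 0.1]),
            "age_group": rng.choice(list(AGE_GROUPS) + ["missing"], n_rows),
            "cause_group": rng.choice(causes, n_rows),
            "deaths": rng.integers(0, 50, n_rows),
        }))
    return pd.concat(frames, ignore_index=True)


class TestConservation:
    def test_exact_conservation_on_randomized_tables(self):
        rng = np.random.default_rng(12)
        t = random_tables(1000, rng)
        before = t.groupby("country_id")["deaths"].sum()
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = preprocess(t, seed=99)
        after = out.groupby("country_id")["deaths"].sum()
        after = after.reindex(before.index).fillna(0).astype(int)
        assert (before == after).all()
        assert not (out.sex == "missing").any()
        assert not (out.age_group == "missing").any()
        assert set(out.cause_group) <= set(CAUSE_GROUPS)

    def test_idempotent_on_clean_table(self):
        t = rows(base_row(), base_row(sex="M", cause="CANCER", deaths=3))
        out = preprocess(t, seed=1)
        pd.testing.assert_frame_equal(
            out.sort_values(COLS[:-1]).reset_index(drop=True),
            t.sort_values(COLS[:-1]).reset_index(drop=True),
        )

    def test_redistributed_proportions_track_generator_mix(self, small_panel):
        # after the full chain, cause shares approach the generator's
        # age-marginal mix within each age group
        import warnings

        from citymort.synthetic import default_cause_mix

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clean = preprocess(small_panel.deaths, seed=21)
        sub = clean[clean.age_group == "65-69"]
        got = (sub.groupby("cause_group")["deaths"].sum()
               .reindex(list(CAUSE_GROUPS)).fillna(0))
        got = (got / got.sum()).to_numpy()
        np.testing.assert_allclose(got, default_cause_mix()[14], atol=0.03)


class TestSummaries:
    def test_ill_defined_fractions(self):
        t = rows(base_row(deaths=970), base_row(cause="ILLDEF_DISEASE", deaths=30))
        s = summarize_ill_defined(t)
        assert s.frac_ill_defined_disease.iloc[0] == pytest.approx(0.03)
        assert s.frac_ill_defined_injury.iloc[0] == 0.0

    def test_all_ill_defined(self):
        t = rows(base_row(cause="ILLDEF_DISEASE", deaths=5))
        assert summarize_ill_defined(t).frac_ill_defined.iloc[0] == 1.0


class TestCauseMap:
    def test_chapter_level_assignment(self):
        codes = pd.Series(["I219", "C61", "A09", "X954", "R99", "Y34", "J12"])
        got = assign_cause_groups(codes).tolist()
        assert got == ["CVD_NCD", "CANCER", "CMNN", "VIOLENT",
                       "ILLDEF_DISEASE", "ILLDEF_INJURY", "CMNN"]
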