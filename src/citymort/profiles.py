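"""Proportionate mortality, age-standardized rates and city predictors.

The mortality profile of a city is the share of deaths in each of the
five cause groups: PM_ij = deaths_ij / sum_i deaths_ij.  A secondary
variant (AAPM) replaces raw counts with age-adjusted cause-specific
rates, standardized to the WHO 2000-2025 world standard population, so
that profile differences between cities are not driven by age structure.

Also here: the two registration-coverage corrections (descriptive
up-weighting of deaths versus model-side down-weighting of population),
the social environment index (sum of z-scores of education, water and
sewage access and reversed overcrowding), predictor centering/scaling
with the log-population convention, and the 5-year city growth measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ages import AGE_GROUPS, CAUSE_GROUPS, N_AGE

PM_SUM_TOL = 1e-12


def who_standard() -> pd.Series:
    """WHO 2000-2025 world standard population on the 17-group grid.

    The published standard's 0-4 share is split 1/5 vs 4/5 between ages
    0 and 1-4 (uniform within the group); groups above 75 are collapsed
    into the open interval.  Weights are normalized to sum to 1.
    """
    from importlib.resources import files

    path = files("citymort.data").joinpath("who_standard.csv")
    s = pd.read_csv(path).set_index("age_group")["weight"]
    s = s.reindex(list(AGE_GROUPS))
    return s / s.sum()


def proportionate_mortality(deaths_by_cause: pd.DataFrame) -> pd.DataFrame:
    """Per-city proportionate mortality over the five cause groups.

    ``deaths_by_cause``: long frame (city_id, cause_group, deaths);
    ill-defined causes must already be redistributed.  Cities with zero
    total deaths are emitted as missing rows (PM undefined).
    """
    pivot = (deaths_by_cause.groupby(["city_id", "cause_group"])["deaths"].sum()
             .unstack(fill_value=0.0)
             .reindex(columns=list(CAUSE_GROUPS), fill_value=0.0))
    totals = pivot.sum(axis=1)
    pm = pivot.div(totals, axis=0)
    pm[totals == 0] = np.nan
    pm["flavor"] = "PM"
    return pm.reset_index()


def age_adjusted_rate(
    deaths_by_age: np.ndarray,
    pop_by_age: np.ndarray,
    standard_weights: np.ndarray | None = None,
) -> float:
    """Direct age standardization, per 100,000 person-years.

    Weighted average of the age-specific rates D_k/N_k with weights from
    the standard population (normalized to 1).  Age groups with zero
    population contribute zero deaths or raise.
    """
    d = np.asarray(deaths_by_age, dtype=float)
    n = np.asarray(pop_by_age, dtype=float)
    if d.shape != (N_AGE,) or n.shape != (N_AGE,):
        raise ValueError(f"expected {N_AGE} age groups")
    w = who_standard().to_numpy() if standard_weights is None else (
        np.asarray(standard_weights, dtype=float))
    w = w / w.sum()
    rates = np.zeros(N_AGE)
    ok = n > 0
    if np.any(d[~ok] > 0):
        raise ValueError("deaths in an age group with zero population")
    rates[ok] = d[ok] / n[ok]
    return float(np.sum(w * rates) * 100_000.0)


def aapm(adjusted_rates_by_cause: pd.DataFrame) -> pd.DataFrame:
    """Age-adjusted proportionate mortality: each cause's age-adjusted
    rate divided by the sum over causes, per city.

    ``adjusted_rates_by_cause``: (city_id, cause_group, rate) long frame.
    """
    pivot = (adjusted_rates_by_cause
             .pivot(index="city_id", columns="cause_group", values="rate")
             .reindex(columns=list(CAUSE_GROUPS), fill_value=0.0))
    totals = pivot.sum(axis=1)
    out = pivot.div(totals, axis=0)
    out[totals == 0] = np.nan
    out["flavor"] = "AAPM"
    return out.reset_index()


def profile_table(
    deaths: pd.DataFrame,
    population: pd.DataFrame,
    coverage: pd.DataFrame | None = None,
    sex_stratified: bool = False,
) -> pd.DataFrame:
    """PM and AAPM per city (sexes combined by default).

    ``deaths``: preprocessed table; ``population``: census schema (the
    two time points are averaged into mid-period exposure); ``coverage``:
    optional (city_id, sex, phi) used to up-weight observed deaths by
    1/phi (the descriptive correction).
    """
    deaths = deaths.copy()
    if coverage is not None:
        cov = coverage.drop_duplicates(["city_id", "sex"]).set_index(["city_id", "sex"])["phi"]
        w = deaths.set_index(["city_id", "sex"]).index.map(cov)
        deaths["deaths"] = deaths["deaths"] / np.asarray(w, dtype=float)

    group_sex = ["sex"] if sex_stratified else []
    pm = []
    aapm_rates = []
    pop_mid = (population.groupby(["city_id", "sex", "age_group"])["population"]
               .mean().reset_index())
    for keys, sub in deaths.groupby(["city_id"] + group_sex):
        city = keys[0] if isinstance(keys, tuple) else keys
        psub = pop_mid[pop_mid.city_id == city]
        if sex_stratified:
            psub = psub[psub.sex == keys[1]]
        n = (psub.groupby("age_group")["population"].sum()
             .reindex(list(AGE_GROUPS)).fillna(0.0).to_numpy())
        for cause in CAUSE_GROUPS:
            csub = sub[sub.cause_group == cause]
            d = (csub.groupby("age_group")["deaths"].sum()
                 .reindex(list(AGE_GROUPS)).fillna(0.0).to_numpy())
            row = dict(city_id=city, cause_group=cause,
                       deaths=float(d.sum()),
                       rate=age_adjusted_rate(d, n))
            if sex_stratified:
                row["sex"] = keys[1]
            aapm_rates.append(row)
    rates = pd.DataFrame(aapm_rates)

    idx = ["city_id"] + group_sex
    tot = rates.groupby(idx)[["deaths", "rate"]].sum().rename(
        columns={"deaths": "tot_d", "rate": "tot_r"})
    out = rates.join(tot, on=idx)
    out["pm"] = np.where(out.tot_d > 0, out.deaths / out.tot_d, np.nan)
    out["aapm"] = np.where(out.tot_r > 0, out.rate / out.tot_r, np.nan)
    return out[idx + ["cause_group", "pm", "aapm"]]


def coverage_reweight(
    deaths: np.ndarray | pd.Series,
    population: np.ndarray | pd.Series,
    coverage: float | np.ndarray,
    mode: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the registration-coverage correction.

    ``descriptive`` divides deaths by coverage (corrected deaths =
    observed / c), used for descriptive rates; ``model`` multiplies the
    population by coverage (corrected population = observed * c), used as
    the exposure in count models so precision is not inflated.  The two
    modes give identical crude rates and are never combined.
    """
    d = np.asarray(deaths, dtype=float)
    n = np.asarray(population, dtype=float)
    c = np.asarray(coverage, dtype=float)
    if np.any((c <= 0) | (c > 1)):
        raise ValueError("coverage must be in (0, 1]")
    if mode == "descriptive":
        return d / c, n
    if mode == "model":
        return d, n * c
    raise ValueError(f"mode must be 'descriptive' or 'model', got {mode!r}")


def social_environment_index(
    education: np.ndarray,
    water: np.ndarray,
    sewage: np.ndarray,
    overcrowding: np.ndarray,
) -> np.ndarray:
    """Sum of z-scores of education, water and sewage access, minus the
    z-score of overcrowding; higher values mean better social conditions.
    Zero-mean across cities by construction."""
    def z(v):
        v = np.asarray(v, dtype=float)
        sd = v.std(ddof=0)
        if sd == 0:
            raise ValueError("constant column has no z-score")
        return (v - v.mean()) / sd

    return z(education) + z(water) + z(sewage) - z(overcrowding)


@dataclass
class ScalingInfo:
    means: pd.Series
    sds: pd.Series
    log_columns: list


def scale_predictors(
    table: pd.DataFrame,
    log_columns: tuple[str, ...] = ("population",),
    skip: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, ScalingInfo]:
    """Center and scale predictors by their overall mean and s.d.;
    population is natural-log transformed instead (not scaled), so its
    coefficient is per log-unit of city size.

    Raises on constant columns (zero s.d. has no scale).
    """
    out = table.copy()
    num = out.select_dtypes("number").columns
    means, sds = {}, {}
    for col in num:
        if col in skip:
            continue
        if col in log_columns:
            if (out[col] <= 0).any():
                raise ValueError(f"log transform requires positive {col}")
            out[col] = np.log(out[col])
            continue
        sd = out[col].std(ddof=0)
        if sd == 0:
            raise ValueError(f"column {col!r} is constant; cannot scale")
        means[col], sds[col] = out[col].mean(), sd
        out[col] = (out[col] - means[col]) / sd
    info = ScalingInfo(pd.Series(means), pd.Series(sds), list(log_columns))
    return out, info


def effect_per_pct_larger(beta_log: float, pct: float = 50.0) -> float:
    """Translate a log-population coefficient into the effect of a city
    pct% larger: beta * ln(1 + pct/100)."""
    return float(beta_log * np.log1p(pct / 100.0))


def city_growth(pop_t1: float | np.ndarray, pop_t2: float | np.ndarray) -> np.ndarray:
    """Population growth over the 5-year window, in percent:
    (P2/P1 - 1) * 100.  Also used with an earlier window for the
    growth-timing sensitivity analysis."""
    p1 = np.asarray(pop_t1, dtype=float)
    p2 = np.asarray(pop_t2, dtype=float)
    if np.any(p1 <= 0):
        raise ValueError("baseline population must be positive")
    return (p2 / p1 - 1.0) * 100.0
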