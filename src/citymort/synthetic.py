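"""Synthetic vital-registration panels with known ground truth.

Emulates the raw material of a multi-country city mortality study: for
each city, a parametric (Siler) age/sex mortality schedule, a stable
population enumerated at the two endpoints of a 5-year window, Poisson
death generation, binomial under-registration with city/sex-specific
coverage, a five-group cause-of-death mix contaminated with ill-defined
codes, and missing age/sex at configurable rates.  Every corruption is
recorded in a per-city truth object so downstream estimators (coverage
ensembles, the Bayesian rate model, life tables, profiles) can be scored
against a known answer.

The generator is the study-conditions oracle, not a fixture: defaults are
chosen once to resemble Latin-American-scale cities (populations in the
hundreds of thousands, life expectancy at birth between 60 and 85 years,
registration coverage between 60% and 100%, ~3% ill-defined deaths,
~0.5% missing age and ~0.2% missing sex).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ages import (
    AGE_GROUPS,
    AGE_LOWER,
    AGE_MID,
    CAUSE_GROUPS,
    DISEASE_CAUSES,
    ILLDEF_DISEASE,
    ILLDEF_INJURY,
    MISSING,
    N_AGE,
    SEXES,
)

DEATH_COLUMNS = [
    "country_id", "city_id", "year", "sex", "age_group", "cause_group", "deaths",
]
POP_COLUMNS = ["country_id", "city_id", "sex", "age_group", "time", "population"]

#: default 5-year study window (deaths summed over these calendar years)
DEFAULT_YEARS = tuple(range(2012, 2017))


@dataclass(frozen=True)
class SilerParams:
    """Siler hazard m(x) = a*exp(-b*x) + c + d*exp(e*x).

    The three terms capture infant/child mortality decline, a background
    (accident) hazard, and senescent (Gompertz) mortality.
    """

    a: float
    b: float
    c: float
    d: float
    e: float

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d, self.e) <= 0:
            raise ValueError("Siler parameters must be positive")

    def hazard(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a * np.exp(-self.b * x) + self.c + self.d * np.exp(self.e * x)


#: Defaults give e0 ~ 83 (F) and ~ 74 (M) at level 1; see docs/methods.md.
DEFAULT_SILER = {
    "F": SilerParams(a=0.012, b=1.1, c=0.0006, d=1.0e-5, e=0.105),
    "M": SilerParams(a=0.016, b=1.0, c=0.0012, d=1.8e-5, e=0.103),
}


@dataclass(frozen=True)
class MortalitySchedule:
    """Central death rates on the 17-group abridged grid for one sex."""

    sex: str
    rates: np.ndarray  # length 17, deaths per person-year

    def __post_init__(self):
        r = np.asarray(self.rates, dtype=float)
        if r.shape != (N_AGE,):
            raise ValueError(f"expected {N_AGE} rates, got {r.shape}")
        if np.any(~np.isfinite(r)) or np.any(r < 0):
            raise ValueError("rates must be finite and non-negative")
        object.__setattr__(self, "rates", r)

    @property
    def age_groups(self) -> tuple[str, ...]:
        return AGE_GROUPS


def make_schedule(
    level: float,
    params: SilerParams | None = None,
    sex: str = "F",
) -> MortalitySchedule:
    """Siler mortality schedule evaluated at group midpoints, scaled by level.

    ``level`` is a proportional scaling of the whole schedule; level=1 is
    the default schedule, level=0 gives zero rates, negative levels are
    rejected.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    if params is None:
        params = DEFAULT_SILER[sex]
    rates = level * params.hazard(AGE_MID)
    return MortalitySchedule(sex=sex, rates=rates)


def stable_population(
    schedule: MortalitySchedule, growth_rate: float, total: float
) -> np.ndarray:
    """Age distribution of a stable population with the given schedule
    and exponential growth rate, scaled to the requested total.

    The schedule is treated as a piecewise-constant hazard, so the
    continuous stable-population density B*l(a)*exp(-r*a) is integrated
    on a fine grid within each group.  In this construction group deaths
    equal rate times person-years exactly, which is what makes the
    generated panels satisfy the death-distribution methods' balance
    identities by construction.
    """
    rates = np.maximum(schedule.rates, 1e-10)
    bounds = np.append(AGE_LOWER, 110.0)  # open interval integrated to 110
    da = 1.0 / 16.0
    grid = np.arange(0.0, bounds[-1], da)
    idx = np.minimum(np.searchsorted(bounds, grid, side="right") - 1, N_AGE - 1)
    mu = rates[idx]
    # survival at grid midpoints under the piecewise-constant hazard
    cum = np.concatenate([[0.0], np.cumsum(mu * da)])
    l_mid = np.exp(-(cum[:-1] + mu * da / 2.0))
    f = l_mid * np.exp(-growth_rate * (grid + da / 2.0))
    shape = np.zeros(N_AGE)
    np.add.at(shape, idx, f * da)
    # analytic tail beyond the integration horizon
    tail_decay = rates[-1] + growth_rate
    if tail_decay > 1e-12:
        l_end = np.exp(-cum[-1])
        shape[-1] += l_end * np.exp(-growth_rate * bounds[-1]) / tail_decay
    return total * shape / shape.sum()


def project_population(
    base_population: np.ndarray,
    growth_rate: float,
    years: float,
    mode: str = "exponential",
    schedule: MortalitySchedule | None = None,
    migration: np.ndarray | None = None,
) -> np.ndarray:
    """Population at the end of an interval, from the start-of-interval one.

    ``exponential`` mode scales every cell by exp(growth_rate * years) —
    the stable-population case in which the death-distribution methods'
    assumptions hold exactly.  ``cohort`` mode ages the population forward
    through the schedule in 5-year steps (requires years to be a multiple
    of 5 and a schedule), with births set to keep the youngest groups
    growing at ``growth_rate``.  ``migration``, if given, is a per-age
    additive perturbation (applied once, at the end) used to violate the
    no-migration assumption on demand.
    """
    base = np.asarray(base_population, dtype=float)
    if base.shape != (N_AGE,):
        raise ValueError(f"expected {N_AGE} age groups, got {base.shape}")
    if np.any(base < 0):
        raise ValueError("populations must be non-negative")
    if years <= 0:
        raise ValueError("years must be > 0")

    if mode == "exponential":
        out = base * np.exp(growth_rate * years)
    elif mode == "cohort":
        if schedule is None:
            raise ValueError("cohort mode requires a schedule")
        if years % 5:
            raise ValueError("cohort mode requires a multiple of 5 years")
        out = base.copy()
        for _ in range(int(years) // 5):
            surv = np.exp(-5.0 * schedule.rates)
            nxt = np.zeros_like(out)
            # ages 0 and 1-4 jointly feed 5-9; thereafter 5-year shifts
            nxt[2] = (out[0] * np.exp(-schedule.rates[0])
                      + out[1] * np.exp(-4.0 * schedule.rates[1])) * 1.0
            nxt[3:-1] = out[2:-2] * surv[2:-2]
            nxt[-1] = out[-2] * surv[-2] + out[-1] * surv[-1]
            # replenish the youngest groups at the nominal growth rate
            nxt[0] = out[0] * np.exp(growth_rate * 5.0)
            nxt[1] = out[1] * np.exp(growth_rate * 5.0)
            out = nxt
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if migration is not None:
        out = out + np.asarray(migration, dtype=float)
    if np.any(out < 0):
        raise ValueError("projection produced negative population")
    return out


@dataclass
class CityTruth:
    """Everything the generator knows about one city."""

    country_id: str
    city_id: str
    base_population: dict  # sex -> length-17 array at t1
    growth_rate: float
    coverage: dict  # sex -> c_true in (0, 1]
    schedules: dict  # sex -> MortalitySchedule
    cause_mix: dict  # sex -> (17, 5) rows summing to 1
    ill_defined_rate: float = 0.0
    missing_age_rate: float = 0.0
    missing_sex_rate: float = 0.0

    def __post_init__(self):
        for s in SEXES:
            c = self.coverage[s]
            if not (0.0 < c <= 1.0):
                raise ValueError(f"coverage must be in (0, 1], got {c}")
            mix = np.asarray(self.cause_mix[s], dtype=float)
            if mix.shape != (N_AGE, len(CAUSE_GROUPS)):
                raise ValueError("cause_mix must be (17, 5) per sex")
            if not np.allclose(mix.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("cause_mix rows must sum to 1")
            self.cause_mix[s] = mix
        for r in (self.ill_defined_rate, self.missing_age_rate, self.missing_sex_rate):
            if not (0.0 <= r < 1.0):
                raise ValueError("corruption rates must be in [0, 1)")


@dataclass
class SyntheticPanel:
    """Observed and true death tables plus census pair and per-city truth."""

    deaths: pd.DataFrame        # registered, after all corruption
    deaths_true: pd.DataFrame   # complete and uncorrupted
    census: pd.DataFrame        # population by city/sex/age at t1 and t2
    truth: list[CityTruth]
    years: tuple[int, ...] = DEFAULT_YEARS

    @property
    def t1(self) -> float:
        return float(self.years[0])

    @property
    def t2(self) -> float:
        return float(self.years[0] + len(self.years))

    def person_years(self, city_id: str, sex: str, mode: str = "geometric") -> np.ndarray:
        """Window person-years by age for one city and sex.

        ``geometric`` (default): T * sqrt(N1 * N2) cell-wise, the same
        convention the death-distribution estimators use (and the exact
        mid-period population under exponential growth); ``arithmetic``:
        T * (N1 + N2) / 2.
        """
        sub = self.census[(self.census.city_id == city_id) & (self.census.sex == sex)]
        n1 = (sub[sub.time == self.t1].set_index("age_group")
              .reindex(list(AGE_GROUPS))["population"].to_numpy())
        n2 = (sub[sub.time == self.t2].set_index("age_group")
              .reindex(list(AGE_GROUPS))["population"].to_numpy())
        T = self.t2 - self.t1
        if mode == "geometric":
            return T * np.sqrt(n1 * n2)
        if mode == "arithmetic":
            return T * (n1 + n2) / 2.0
        raise ValueError(f"unknown person-years mode {mode!r}")


def _city_rng(master_seed: int, country_idx: int, city_idx: int) -> np.random.Generator:
    # one stream per city: adding cities never perturbs existing ones
    ss = np.random.SeedSequence(master_seed, spawn_key=(country_idx, city_idx))
    return np.random.default_rng(ss)


def _simulate_city(
    truth: CityTruth,
    rng: np.random.Generator,
    years: tuple[int, ...],
    person_years_mode: str = "geometric",
) -> tuple[list[dict], list[dict]]:
    """True and observed death rows for one city."""
    T = float(len(years))
    true_rows: list[dict] = []
    obs_rows: list[dict] = []
    n_cause = len(CAUSE_GROUPS)

    for sex in SEXES:
        n1 = np.asarray(truth.base_population[sex], dtype=float)
        n2 = project_population(n1, truth.growth_rate, T)
        if person_years_mode == "geometric":
            py = T * np.sqrt(n1 * n2)
        elif person_years_mode == "arithmetic":
            py = T * (n1 + n2) / 2.0
        else:
            raise ValueError(f"unknown person-years mode {person_years_mode!r}")
        rates = truth.schedules[sex].rates
        mix = truth.cause_mix[sex]
        cov = truth.coverage[sex]

        for year in years:
            # true deaths per (age, cause) cell for this calendar year
            n_age_deaths = rng.poisson(py / T * rates)
            for k in range(N_AGE):
                d = int(n_age_deaths[k])
                if d == 0:
                    continue
                by_cause = rng.multinomial(d, mix[k])
                for c in range(n_cause):
                    if by_cause[c] == 0:
                        continue
                    true_rows.append(
                        dict(country_id=truth.country_id, city_id=truth.city_id,
                             year=year, sex=sex, age_group=AGE_GROUPS[k],
                             cause_group=CAUSE_GROUPS[c], deaths=int(by_cause[c]))
                    )
                    # under-registration: each true death observed w.p. coverage
                    reg = int(rng.binomial(by_cause[c], cov))
                    if reg == 0:
                        continue
                    # ill-defined miscoding within the registered deaths
                    cause = CAUSE_GROUPS[c]
                    if truth.ill_defined_rate > 0:
                        bad = int(rng.binomial(reg, truth.ill_defined_rate))
                    else:
                        bad = 0
                    good = reg - bad
                    targets = []
                    if good:
                        targets.append((cause, good))
                    if bad:
                        ill = (ILLDEF_DISEASE if cause in DISEASE_CAUSES
                               else ILLDEF_INJURY)
                        targets.append((ill, bad))
                    for cause_out, cnt in targets:
                        # blank sex, then age, independently per death
                        miss_sex = (int(rng.binomial(cnt, truth.missing_sex_rate))
                                    if truth.missing_sex_rate > 0 else 0)
                        for sex_out, cnt_s in ((sex, cnt - miss_sex), (MISSING, miss_sex)):
                            if cnt_s == 0:
                                continue
                            miss_age = (int(rng.binomial(cnt_s, truth.missing_age_rate))
                                        if truth.missing_age_rate > 0 else 0)
                            for age_out, cnt_a in (
                                (AGE_GROUPS[k], cnt_s - miss_age),
                                (MISSING, miss_age),
                            ):
                                if cnt_a == 0:
                                    continue
                                obs_rows.append(
                                    dict(country_id=truth.country_id,
                                         city_id=truth.city_id, year=year,
                                         sex=sex_out, age_group=age_out,
                                         cause_group=cause_out, deaths=cnt_a)
                                )
    return true_rows, obs_rows


def simulate_deaths(
    cities: list[CityTruth],
    seed: int | None,
    years: tuple[int, ...] = DEFAULT_YEARS,
    person_years_mode: str = "geometric",
) -> SyntheticPanel:
    """Generate a full synthetic panel from a list of city truths.

    A seed is mandatory: the reproducibility contract is that the same
    (cities, seed) pair always yields the identical panel.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducibility")

    T = float(len(years))
    t1, t2 = float(years[0]), float(years[0] + len(years))
    true_rows: list[dict] = []
    obs_rows: list[dict] = []
    pop_rows: list[dict] = []

    country_order: dict[str, int] = {}
    city_counter: dict[str, int] = {}
    for truth in cities:
        ci = country_order.setdefault(truth.country_id, len(country_order))
        ji = city_counter.get(truth.country_id, 0)
        city_counter[truth.country_id] = ji + 1
        rng = _city_rng(seed, ci, ji)
        tr, ob = _simulate_city(truth, rng, years, person_years_mode)
        true_rows.extend(tr)
        obs_rows.extend(ob)
        for sex in SEXES:
            n1 = np.asarray(truth.base_population[sex], dtype=float)
            n2 = project_population(n1, truth.growth_rate, T)
            for time, n in ((t1, n1), (t2, n2)):
                for k in range(N_AGE):
                    pop_rows.append(
                        dict(country_id=truth.country_id, city_id=truth.city_id,
                             sex=sex, age_group=AGE_GROUPS[k], time=time,
                             population=float(n[k]))
                    )

    def _frame(rows: list[dict]) -> pd.DataFrame:
        if not rows:
            return pd.DataFrame(columns=DEATH_COLUMNS).astype({"deaths": int})
        df = pd.DataFrame(rows, columns=DEATH_COLUMNS)
        # merge duplicate cells created by the per-cause corruption loop
        df = (df.groupby(DEATH_COLUMNS[:-1], as_index=False, sort=True)["deaths"]
              .sum())
        return df

    return SyntheticPanel(
        deaths=_frame(obs_rows),
        deaths_true=_frame(true_rows),
        census=pd.DataFrame(pop_rows, columns=POP_COLUMNS),
        truth=cities,
        years=tuple(years),
    )


def default_cause_mix() -> np.ndarray:
    """Age-specific cause-group mix (17 x 5), roughly epidemiological:
    CMNN-heavy in childhood, injury-heavy in young adults, dominated by
    CVD/NCD and cancer at older ages."""
    mix_by_block = {
        (0, 1): (0.55, 0.05, 0.25, 0.12, 0.03),
        (2, 3): (0.30, 0.15, 0.20, 0.25, 0.10),
        (4, 5, 6): (0.15, 0.10, 0.15, 0.25, 0.35),
        (7, 8): (0.15, 0.15, 0.30, 0.20, 0.20),
        (9, 10, 11): (0.10, 0.25, 0.45, 0.12, 0.08),
        (12, 13, 14, 15): (0.08, 0.28, 0.55, 0.06, 0.03),
        (16,): (0.08, 0.20, 0.65, 0.05, 0.02),
    }
    mix = np.zeros((N_AGE, len(CAUSE_GROUPS)))
    for block, probs in mix_by_block.items():
        for k in block:
            mix[k] = probs
    return mix


def make_panel_truths(
    n_countries: int = 2,
    cities_per_country: int = 5,
    seed: int = 0,
    coverage_range: tuple[float, float] = (0.6, 1.0),
    growth_range: tuple[float, float] = (0.005, 0.025),
    mean_population: float = 300_000.0,
    ill_defined_rate: float = 0.03,
    missing_age_rate: float = 0.005,
    missing_sex_rate: float = 0.002,
    city_level_sd: float = 0.10,
    city_tilt_sd: float = 0.05,
) -> list[CityTruth]:
    """Draw a standard multi-country panel of city truths.

    Country mortality levels vary around the default schedules; each city
    then gets a lognormal level multiplier and a smooth age tilt so city
    schedules deviate from their country pattern gradually across age —
    the regime the hierarchical model is designed for.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(9999,)))
    truths = []
    for i in range(n_countries):
        country = f"C{i + 1}"
        country_level = float(np.exp(rng.normal(0.0, 0.12)))
        for j in range(cities_per_country):
            level = country_level * float(np.exp(rng.normal(0.0, city_level_sd)))
            tilt = float(rng.normal(0.0, city_tilt_sd))
            growth = float(rng.uniform(*growth_range))
            total = float(mean_population * np.exp(rng.normal(0.0, 0.5)))
            schedules, base_pop, coverage = {}, {}, {}
            cov = {s: float(rng.uniform(*coverage_range)) for s in SEXES}
            for sex in SEXES:
                sched = make_schedule(level, sex=sex)
                rates = sched.rates * np.exp(tilt * (AGE_MID - 40.0) / 35.0)
                schedules[sex] = MortalitySchedule(sex=sex, rates=rates)
                base_pop[sex] = stable_population(schedules[sex], growth, total / 2.0)
                coverage[sex] = cov[sex]
            truths.append(
                CityTruth(
                    country_id=country,
                    city_id=f"{country}-{j + 1:02d}",
                    base_population=base_pop,
                    growth_rate=growth,
                    coverage=coverage,
                    schedules=schedules,
                    cause_mix={s: default_cause_mix() for s in SEXES},
                    ill_defined_rate=ill_defined_rate,
                    missing_age_rate=missing_age_rate,
                    missing_sex_rate=missing_sex_rate,
                )
            )
    return truths


def write_panel(panel: SyntheticPanel, outdir: str | Path) -> dict[str, Path]:
    """Write deaths.csv, population.csv and truth.json to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "deaths": outdir / "deaths.csv",
        "deaths_true": outdir / "deaths_true.csv",
        "population": outdir / "population.csv",
        "truth": outdir / "truth.json",
    }
    panel.deaths.to_csv(paths["deaths"], index=False)
    panel.deaths_true.to_csv(paths["deaths_true"], index=False)
    panel.census.to_csv(paths["population"], index=False)
    blob = []
    for t in panel.truth:
        d = asdict(t)
        d["base_population"] = {s: list(map(float, v)) for s, v in t.base_population.items()}
        d["schedules"] = {s: list(map(float, t.schedules[s].rates)) for s in SEXES}
        d["cause_mix"] = {s: np.asarray(v).tolist() for s, v in t.cause_mix.items()}
        blob.append(d)
    paths["truth"].write_text(json.dumps({"years": list(panel.years), "cities": blob}, indent=1))
    return paths
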