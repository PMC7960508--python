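"""Death-registration completeness by death-distribution methods.

Estimates the fraction of deaths captured by a vital-registration system
for one city and sex, from population counts at two time points and the
deaths registered in between.  Three estimators are provided:

* **GGB** (generalized growth balance): over open age intervals a+, the
  balance identity b(a+) - r(a+) = d(a+)/c holds when registration has
  constant completeness c; a line fitted to (d, b - r) has slope 1/c and
  an intercept that absorbs any relative coverage drift between the two
  censuses.
* **SEG** (synthetic extinct generations): reconstructs the flow of
  persons attaining each exact age from registered deaths above that age
  adjusted for growth; the ratio of reconstructed to enumerated flows
  estimates c.
* **hybrid**: GGB first, to estimate the census-coverage drift; censuses
  are reconciled and SEG applied to the adjusted data.

Each method runs over three age bands (an automatically chosen
best-fitting band plus the conventional 30-65 and 50-70 bands), giving
nine estimates per city and sex.  Their harmonic mean phi and sample
variance s^2 are moment-matched into a Beta(K*phi, K*(1-phi)) prior with
K = phi*(1-phi)/s^2 - 1, which carries registration uncertainty into the
Bayesian mortality model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ages import DDM_AGE_LOWER, collapse_to_ddm
from .lifetables import abridged_life_table
from .synthetic import DEFAULT_SILER, make_schedule

#: conventional manual age bands (exact-age lower/upper fit points)
HILL_BAND = (30, 65)
MURRAY_BAND = (50, 70)

#: clamp window for individual estimates before ensembling
CLAMP_LO, CLAMP_HI = 0.3, 1.0

#: variance floor when all nine estimates coincide
S2_FLOOR = 1e-6


def standard_e75(sex: str) -> float:
    """Remaining life expectancy at 75 from the bundled standard schedule.

    Seeds the SEG open-interval reconstruction; under zero growth the
    seed is insensitive to this value, and sensitivity grows only as
    exp(r * e75) for growth rate r.
    """
    sched = make_schedule(1.0, DEFAULT_SILER[sex], sex=sex)
    lt = abridged_life_table(sched.rates, sex=sex)
    return float(lt.e[-1])


@dataclass(frozen=True)
class CensusPair:
    """Population by 5-year age group (0-4 ... 75+) at two time points."""

    n1: np.ndarray
    n2: np.ndarray
    t1: float
    t2: float

    def __post_init__(self):
        n1 = np.asarray(self.n1, dtype=float)
        n2 = np.asarray(self.n2, dtype=float)
        if n1.shape != n2.shape or n1.shape != DDM_AGE_LOWER.shape:
            raise ValueError(
                f"censuses must both have {DDM_AGE_LOWER.size} five-year groups"
            )
        if np.any(n1 < 0) or np.any(n2 < 0):
            raise ValueError("populations must be non-negative")
        if self.t2 <= self.t1:
            raise ValueError("t2 must exceed t1")
        object.__setattr__(self, "n1", n1)
        object.__setattr__(self, "n2", n2)

    @property
    def T(self) -> float:
        return self.t2 - self.t1

    @classmethod
    def from_17(cls, n1_17, n2_17, t1: float, t2: float) -> "CensusPair":
        """Collapse 17-group populations (0 and 1-4 separate) to the DDM grid."""
        return cls(collapse_to_ddm(n1_17), collapse_to_ddm(n2_17), t1, t2)


def _check_deaths(deaths_by_age: np.ndarray) -> np.ndarray:
    d = np.asarray(deaths_by_age, dtype=float)
    if d.shape != DDM_AGE_LOWER.shape:
        raise ValueError(f"deaths must have {DDM_AGE_LOWER.size} five-year groups")
    if np.any(d < 0):
        raise ValueError("deaths must be non-negative")
    return d


def _band_points(age_band: tuple[int, int]) -> np.ndarray:
    lo, hi = age_band
    pts = np.arange(lo, hi + 1, 5, dtype=int)
    if pts.size < 4:
        raise ValueError("age band must contain at least 4 points")
    if lo < 5 or hi > 75 or lo % 5 or hi % 5:
        raise ValueError("band bounds must be multiples of 5 within [5, 75]")
    return pts


def _entry_group_pops(census: CensusPair, e75_val: float) -> np.ndarray:
    """Geometric-mean group populations used for exact-age entry flows.

    The open 75+ interval is not a 5-year group; for the flow at exact
    age 75 its effective 75-79 population is estimated from the open
    count as N(75+) * (1 - exp(-5/e75)), which is exact when the tail
    hazard is constant at 1/e75.
    """
    geo = np.sqrt(census.n1 * census.n2)
    geo = geo.copy()
    geo[-1] *= 1.0 - np.exp(-5.0 / e75_val)
    return geo


def _exact_age_flow(geo: np.ndarray, i: int) -> float:
    """Persons attaining exact age lower[i] per year, from grouped counts.

    Cubic (four-group) boundary estimate
    f = (-g[i-2] + 7 g[i-1] + 7 g[i] - g[i+1]) / 60,
    exact for cubic densities; near the edges of the grid it falls back
    to the two-group average (g[i-1] + g[i]) / 10, which carries a small
    convexity bias for decaying densities.
    """
    n = geo.shape[0]
    if 2 <= i <= n - 2:
        return float((-geo[i - 2] + 7 * geo[i - 1] + 7 * geo[i] - geo[i + 1]) / 60.0)
    return float((geo[i - 1] + geo[i]) / 10.0)


def _ggb_points(
    census: CensusPair,
    deaths: np.ndarray,
    ages: np.ndarray,
    e75_val: float | None = None,
):
    """x = d(a+), y = b(a+) - r(a+) for each open interval a+ in the band."""
    n1, n2, T = census.n1, census.n2, census.T
    if e75_val is None:
        e75_val = standard_e75("F")
    geo = _entry_group_pops(census, e75_val)
    lower = DDM_AGE_LOWER
    xs, ys = [], []
    for a in ages:
        i = int(np.searchsorted(lower, a))
        if lower[i] != a:
            raise ValueError(f"age {a} not on the 5-year grid")
        N1a, N2a = n1[i:].sum(), n2[i:].sum()
        if N1a <= 0 or N2a <= 0:
            raise ValueError(f"zero open-interval population above age {a}")
        geo_open = np.sqrt(N1a * N2a)
        b = _exact_age_flow(geo, i) / geo_open
        r = np.log(N2a / N1a) / T
        d = deaths[i:].sum() / (T * geo_open)
        xs.append(d)
        ys.append(b - r)
    return np.array(xs), np.array(ys)


def _orthogonal_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Total-least-squares line y = intercept + slope * x.

    Returns (slope, intercept, rmse of orthogonal residuals).
    """
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    syy = np.sum((y - ym) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    if sxy == 0:
        slope = 0.0 if syy <= sxx else np.inf
    else:
        slope = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)
    intercept = ym - slope * xm
    if not np.isfinite(slope):
        return slope, intercept, np.inf
    resid = (y - intercept - slope * x) / np.sqrt(1 + slope**2)
    return float(slope), float(intercept), float(np.sqrt(np.mean(resid**2)))


@dataclass(frozen=True)
class GGBResult:
    completeness: float
    delta: float          # intercept: census-coverage drift per year
    slope: float
    rmse: float
    ok: bool = True


def _resolve_e75(e75, sex: str) -> float:
    if e75 is None:
        return standard_e75(sex)
    if isinstance(e75, dict):
        return float(e75[sex])
    return float(e75)


def ggb(
    census: CensusPair,
    deaths_by_age: np.ndarray,
    age_band: tuple[int, int] = HILL_BAND,
    e75: dict[str, float] | float | None = None,
    sex: str = "F",
) -> GGBResult:
    """Generalized growth balance completeness for one city and sex.

    Fits the growth-balance line by orthogonal (total least squares)
    regression over the band; completeness is the reciprocal slope,
    relative to the geometric-mean coverage of the two censuses.  The
    intercept is the relative census-coverage drift per year,
    delta = ln(k1/k2)/T, returned for the hybrid adjustment.
    """
    deaths = _check_deaths(deaths_by_age)
    ages = _band_points(age_band)
    x, y = _ggb_points(census, deaths, ages, e75_val=_resolve_e75(e75, sex))
    slope, intercept, rmse = _orthogonal_fit(x, y)
    if not np.isfinite(slope) or slope <= 0:
        return GGBResult(np.nan, intercept, slope, rmse, ok=False)
    return GGBResult(1.0 / slope, intercept, slope, rmse, ok=True)


def _adjusted_census(census: CensusPair, delta: float) -> CensusPair:
    """Reconcile relative census coverage implied by the GGB intercept.

    delta = ln(k1/k2)/T; scaling the second census by exp(delta * T)
    brings it to the first census's coverage level.
    """
    return CensusPair(
        census.n1, census.n2 * np.exp(delta * census.T), census.t1, census.t2
    )


def seg(
    census: CensusPair,
    deaths_by_age: np.ndarray,
    age_band: tuple[int, int] = HILL_BAND,
    delta_adjust: float | None = None,
    e75: dict[str, float] | float | None = None,
    sex: str = "F",
    summary: str = "median",
) -> float:
    """Synthetic-extinct-generations completeness for one city and sex.

    Reconstructs the annual flow of persons attaining each exact age x
    from registered deaths above x carried backward at the age-specific
    growth rates; the open interval is seeded with
    D(75+) * exp(r * e75) * (1 - (r * e75)^2 / 6) using a remaining life
    expectancy e75 from the bundled standard schedule.  Completeness is
    the median (or mean) of reconstructed over enumerated flows across
    the band.
    """
    deaths = _check_deaths(deaths_by_age)
    ages = _band_points(age_band)
    cen = census if delta_adjust is None else _adjusted_census(census, delta_adjust)
    n1, n2, T = cen.n1, cen.n2, cen.T
    if np.any((n1 <= 0) | (n2 <= 0)):
        raise ValueError("SEG requires positive populations in all groups")
    e75_val = _resolve_e75(e75, sex)

    lower = DDM_AGE_LOWER
    n_grp = lower.size
    geo = _entry_group_pops(cen, e75_val)
    r = np.log(n2 / n1) / T          # group-specific growth
    d_annual = deaths / T

    # flow of persons attaining exact age lower[i], reconstructed.
    # Open-interval seed: with the package's constant-hazard tail
    # convention (remaining lifetime above 75 exponential with mean e75),
    # the exact growth-discount factor is E[exp(-r T)]^-1 = 1 + r * e75;
    # the common series expansion exp(r e75)(1 - (r e75)^2/6) assumes
    # death ages concentrated near e75 and overshoots for a dispersed
    # tail.  The two agree to first order in r * e75.
    nhat = np.zeros(n_grp)
    nhat[-1] = d_annual[-1] * (1.0 + r[-1] * e75_val)
    for i in range(n_grp - 2, -1, -1):
        nhat[i] = nhat[i + 1] * np.exp(5.0 * r[i]) + d_annual[i] * np.exp(2.5 * r[i])

    ratios = []
    for a in ages:
        i = int(np.searchsorted(lower, a))
        entry = _exact_age_flow(geo, i)   # enumerated flow at exact age a
        if entry <= 0:
            raise ValueError(f"zero enumerated flow at age {a}")
        ratios.append(nhat[i] / entry)
    ratios = np.array(ratios)
    if summary == "median":
        return float(np.median(ratios))
    if summary == "mean":
        return float(np.mean(ratios))
    raise ValueError(f"unknown summary {summary!r}")


def hybrid(
    census: CensusPair,
    deaths_by_age: np.ndarray,
    age_band: tuple[int, int] = HILL_BAND,
    e75: dict[str, float] | float | None = None,
    sex: str = "F",
) -> float:
    """GGB-adjusted SEG: estimate census-coverage drift by GGB, reconcile
    the censuses, then apply SEG to the adjusted data."""
    g = ggb(census, deaths_by_age, age_band, e75=e75, sex=sex)
    delta = g.delta if np.isfinite(g.delta) else 0.0
    return seg(census, deaths_by_age, age_band, delta_adjust=delta, e75=e75, sex=sex)


def admissible_bands(
    lo_range: tuple[int, int] = (5, 35),
    hi_range: tuple[int, int] = (50, 75),
    min_width: int = 30,
) -> list[tuple[int, int]]:
    """All contiguous 5-year bands searched by the automatic selection."""
    return [
        (lo, hi)
        for lo in range(lo_range[0], lo_range[1] + 1, 5)
        for hi in range(hi_range[0], hi_range[1] + 1, 5)
        if hi - lo >= min_width
    ]


def choose_age_band_auto(
    census: CensusPair,
    deaths_by_age: np.ndarray,
    e75: dict[str, float] | float | None = None,
    sex: str = "F",
) -> tuple[int, int]:
    """Best-fitting age band: the admissible band minimizing the
    orthogonal-regression RMSE of the GGB line, tie-broken toward the
    widest band and then the lowest starting age."""
    deaths = _check_deaths(deaths_by_age)
    best = None
    for band in admissible_bands():
        res = ggb(census, deaths, band, e75=e75, sex=sex)
        if not np.isfinite(res.rmse):
            continue
        width = band[1] - band[0]
        # minimize rmse; tie-break widest, then lowest start
        key = (round(res.rmse, 12), -width, band[0])
        if best is None or key < best[0]:
            best = (key, band)
    if best is None:
        raise ValueError("no admissible band produced a finite GGB fit")
    return best[1]


@dataclass
class CompletenessPrior:
    """Nine-estimate ensemble moment-matched to a Beta prior."""

    estimates: pd.DataFrame  # columns: method, band_lo, band_hi, estimate
    phi: float
    s2: float
    K: float
    alpha: float
    beta: float
    clamped: bool = False
    warnings: list = field(default_factory=list)


def beta_prior_from_estimates(
    estimates: np.ndarray, denominator: int | None = None
) -> tuple[float, float, float, float, float, list]:
    """Moment-match completeness estimates to Beta shape parameters.

    phi is the harmonic mean of the (clamped) estimates, s^2 their sample
    variance about phi with the nine-estimate denominator, and
    K = phi*(1-phi)/s^2 - 1 so that Beta(K*phi, K*(1-phi)) has mean phi
    and variance s^2 whenever no clamp fires.
    """
    c = np.asarray(estimates, dtype=float)
    c = c[np.isfinite(c)]
    notes = []
    if c.size < 2:
        raise ValueError("need at least 2 valid completeness estimates")
    clipped = np.clip(c, CLAMP_LO, CLAMP_HI)
    if np.any(clipped != c):
        notes.append("estimates clamped to (0.3, 1.0]")
    c = clipped
    phi = c.size / np.sum(1.0 / c)
    m = denominator if denominator is not None else c.size
    s2 = float(np.sum((c - phi) ** 2) / (m - 1))
    if s2 < S2_FLOOR:
        s2 = S2_FLOOR
        notes.append("s2 floored at 1e-6")
    K = phi * (1.0 - phi) / s2 - 1.0
    if K <= 0:
        K = 1.0
        notes.append("K <= 0 clamped to 1")
    phi = float(min(phi, 1.0))
    return phi, s2, float(K), float(K * phi), float(K * (1.0 - phi)), notes


def ensemble(
    census: CensusPair,
    deaths_by_age: np.ndarray,
    sex: str = "F",
    e75: dict[str, float] | float | None = None,
) -> CompletenessPrior:
    """Nine-estimate completeness ensemble for one city and sex.

    Three methods (GGB, SEG, hybrid) crossed with three age bands (the
    automatically chosen best-fitting band, 30-65, 50-70).  GGB failures
    (non-positive slope) are excluded with a warning.
    """
    deaths = _check_deaths(deaths_by_age)
    auto = choose_age_band_auto(census, deaths, e75=e75, sex=sex)
    bands = [("auto", auto), ("hill", HILL_BAND), ("murray", MURRAY_BAND)]
    rows = []
    notes = []
    for band_name, band in bands:
        g = ggb(census, deaths, band, e75=e75, sex=sex)
        if g.ok:
            rows.append(("ggb", band_name, band, g.completeness))
        else:
            notes.append(f"GGB failed (slope <= 0) on band {band}; excluded")
        rows.append(("seg", band_name, band, seg(census, deaths, band, e75=e75, sex=sex)))
        rows.append(("hybrid", band_name, band, hybrid(census, deaths, band, e75=e75, sex=sex)))
    est = pd.DataFrame(
        [
            dict(method=m, band=bn, band_lo=b[0], band_hi=b[1], estimate=v)
            for m, bn, b, v in rows
        ]
    )
    phi, s2, K, a, b, more = beta_prior_from_estimates(
        est["estimate"].to_numpy(), denominator=9
    )
    notes.extend(more)
    for w in notes:
        warnings.warn(w, stacklevel=2)
    return CompletenessPrior(
        estimates=est, phi=phi, s2=s2, K=K, alpha=a, beta=b,
        clamped=bool(more), warnings=notes,
    )


def completeness_table(
    census_frame: pd.DataFrame,
    deaths_frame: pd.DataFrame,
    e75: dict[str, float] | float | None = None,
) -> pd.DataFrame:
    """Run the ensemble for every (city, sex) in long-format inputs.

    ``census_frame`` uses the population.csv schema (country_id, city_id,
    sex, age_group, time, population) on the 17-group grid; deaths are
    aggregated over year and cause to (city, sex, age_group) and collapsed
    to the 16-group DDM grid.  Returns one row per city x sex x method x
    band plus the ensemble phi, s2, K and Beta shapes.
    """
    from .ages import AGE_GROUPS  # 17-group order

    t1, t2 = sorted(census_frame["time"].unique())
    rows = []
    for (country, city, sex), sub in census_frame.groupby(
        ["country_id", "city_id", "sex"], sort=True
    ):
        n1 = (sub[sub.time == t1].set_index("age_group")
              .reindex(list(AGE_GROUPS))["population"].to_numpy())
        n2 = (sub[sub.time == t2].set_index("age_group")
              .reindex(list(AGE_GROUPS))["population"].to_numpy())
        census = CensusPair.from_17(n1, n2, t1, t2)
        dsub = deaths_frame[
            (deaths_frame.city_id == city) & (deaths_frame.sex == sex)
        ]
        d17 = (dsub.groupby("age_group")["deaths"].sum()
               .reindex(list(AGE_GROUPS)).fillna(0.0).to_numpy())
        deaths = collapse_to_ddm(d17)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prior = ensemble(census, deaths, sex=sex, e75=e75)
        for _, r in prior.estimates.iterrows():
            rows.append(
                dict(country_id=country, city_id=city, sex=sex,
                     method=r.method, age_band_lo=r.band_lo,
                     age_band_hi=r.band_hi, estimate=r.estimate,
                     phi=prior.phi, s2=prior.s2, K=prior.K,
                     alpha=prior.alpha, beta=prior.beta)
            )
    return pd.DataFrame(rows)
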