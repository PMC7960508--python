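"""Abridged life tables and posterior life-expectancy summaries.

Rates arrive on the 17-group abridged grid (0, 1-4, 5-year groups, 75+).
Central rates m are converted to death probabilities q through the usual
nax identity q = n*m / (1 + (n - a)*m), with the infant separation factor
a0 taken from the Andreev-Kingkade formulas and a(1-4) fixed at 1.5 years.
The open interval takes q = 1, L = l/m and e = 1/m.

Applied per posterior draw, these tables turn 1,000 sampled mortality
schedules into 1,000 life expectancies per city, sex and reference age,
summarised by the median, the equal-tailed 95% credible interval and the
relative standard error (s.d. over draws divided by the median).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ages import AGE_GROUPS, AGE_LOWER, AGE_WIDTH, N_AGE

RADIX = 100_000.0
REF_AGES = (0, 20, 40, 60)
#: reliability threshold on the relative standard error
RSE_RELIABLE = 0.25


def a0_andreev_kingkade(m0: float, sex: str) -> float:
    """Average years lived in the first year by those dying in it.

    Piecewise-linear in the infant central death rate m0, with the
    sex-specific Andreev-Kingkade coefficients.
    """
    if sex == "M":
        if m0 < 0.02300:
            return 0.14929 - 1.99545 * m0
        if m0 < 0.08307:
            return 0.02832 + 3.26201 * m0
        return 0.29915
    if sex == "F":
        if m0 < 0.01724:
            return 0.14903 - 2.05527 * m0
        if m0 < 0.06891:
            return 0.04667 + 3.88089 * m0
        return 0.31411
    raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")


@dataclass(frozen=True)
class AbridgedLifeTable:
    """Columns of an abridged life table on the 17-group grid."""

    sex: str
    m: np.ndarray  # central death rate
    a: np.ndarray  # average years lived in interval by decedents (nax)
    q: np.ndarray  # probability of dying in interval
    l: np.ndarray  # survivors at interval start (radix 100,000)
    d: np.ndarray  # deaths in interval
    L: np.ndarray  # person-years lived in interval
    T: np.ndarray  # person-years lived above interval start
    e: np.ndarray  # remaining life expectancy at interval start

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_group": AGE_GROUPS,
                "m": self.m,
                "a": self.a,
                "q": self.q,
                "l": self.l,
                "d": self.d,
                "L": self.L,
                "T": self.T,
                "e": self.e,
            }
        )


def _nax(m: np.ndarray, sex: str) -> np.ndarray:
    a = AGE_WIDTH / 2.0
    a[0] = a0_andreev_kingkade(float(m[0]), sex)
    a[1] = 1.5
    a[-1] = np.nan  # open interval handled separately
    return a


def abridged_life_table(m: np.ndarray, sex: str = "F") -> AbridgedLifeTable:
    """Build an abridged life table from 17 central death rates.

    The open 75+ rate must be positive (otherwise the table has an
    infinite tail); closed-interval rates may be zero.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (N_AGE,):
        raise ValueError(f"expected {N_AGE} rates, got shape {m.shape}")
    if np.any(~np.isfinite(m)) or np.any(m < 0):
        raise ValueError("rates must be finite and non-negative")
    if m[-1] <= 0:
        raise ValueError("open-interval (75+) rate must be > 0")

    n = AGE_WIDTH
    a = _nax(m, sex)

    q = np.empty(N_AGE)
    q[:-1] = n[:-1] * m[:-1] / (1.0 + (n[:-1] - a[:-1]) * m[:-1])
    q[:-1] = np.clip(q[:-1], 0.0, 1.0)
    q[-1] = 1.0

    l = np.empty(N_AGE)
    l[0] = RADIX
    for k in range(N_AGE - 1):
        l[k + 1] = l[k] * (1.0 - q[k])
    d = l * q

    L = np.empty(N_AGE)
    # where everyone survives (q=0) L = n*l; general closed form below covers it
    L[:-1] = n[:-1] * (l[:-1] - d[:-1]) + a[:-1] * d[:-1]
    L[-1] = l[-1] / m[-1]

    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / l, 0.0)

    return AbridgedLifeTable(sex=sex, m=m, a=a, q=q, l=l, d=d, L=L, T=T, e=e)


def life_expectancy_at(lt: AbridgedLifeTable, age: int) -> float:
    """Remaining life expectancy e(x) = T(x)/l(x) at a reference age.

    The reference age must sit on a group boundary of the abridged grid
    (0, 20, 40 and 60 are the ones reported downstream).
    """
    idx = np.flatnonzero(AGE_LOWER == float(age))
    if idx.size == 0:
        raise ValueError(f"age {age} is not an abridged group boundary")
    return float(lt.e[idx[0]])


def life_expectancy_draws(
    rates: np.ndarray,
    sex: str,
    ref_ages: tuple[int, ...] = REF_AGES,
) -> np.ndarray:
    """Life expectancies at the reference ages for each draw of rates.

    Parameters
    ----------
    rates : array (n_draws, 17)
        Posterior draws of age-specific central death rates.

    Returns
    -------
    array (n_draws, len(ref_ages))
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    out = np.empty((rates.shape[0], len(ref_ages)))
    for i, m in enumerate(rates):
        lt = abridged_life_table(m, sex=sex)
        for j, x in enumerate(ref_ages):
            out[i, j] = life_expectancy_at(lt, x)
    return out


def summarize_le_draws(draws: np.ndarray) -> dict[str, float]:
    """Median, equal-tailed 95% interval and r.s.e. of one draw vector.

    The relative standard error is the standard deviation over draws
    divided by the median; estimates with r.s.e. below 25% are flagged
    reliable.
    """
    draws = np.asarray(draws, dtype=float)
    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
    sd = float(np.std(draws, ddof=1)) if draws.size > 1 else 0.0
    rse = sd / med if med != 0 else np.inf
    return {
        "median": float(med),
        "lo95": float(lo),
        "hi95": float(hi),
        "se": sd,
        "rse": float(rse),
        "reliable": bool(rse < RSE_RELIABLE),
    }


def le_table(
    lam: np.ndarray,
    city_ids: list[str],
    country_ids: list[str],
    sexes: list[str],
    ref_ages: tuple[int, ...] = REF_AGES,
    return_draws: bool = False,
):
    """Posterior life-expectancy summary table for a whole panel.

    Parameters
    ----------
    lam : array (n_draws, n_city, 17, n_sex)
        Posterior mortality-rate draws.
    city_ids, country_ids : per-city identifiers (length n_city)
    sexes : sex labels matching the last axis

    Returns
    -------
    DataFrame with one row per (city, sex, ref_age): median, lo95, hi95,
    rse and the reliability flag.  With ``return_draws=True`` also returns
    the raw draw array (n_draws, n_city, n_sex, n_ref).
    """
    lam = np.asarray(lam, dtype=float)
    n_draws, n_city, n_age, n_sex = lam.shape
    if n_age != N_AGE or n_city != len(city_ids) or n_sex != len(sexes):
        raise ValueError("lambda draws do not match panel dimensions")

    all_draws = np.empty((n_draws, n_city, n_sex, len(ref_ages)))
    rows = []
    for j in range(n_city):
        for s, sex in enumerate(sexes):
            ed = life_expectancy_draws(lam[:, j, :, s], sex=sex, ref_ages=ref_ages)
            all_draws[:, j, s, :] = ed
            for r, x in enumerate(ref_ages):
                rows.append(
                    {
                        "country_id": country_ids[j],
                        "city_id": city_ids[j],
                        "sex": sex,
                        "ref_age": x,
                        **summarize_le_draws(ed[:, r]),
                    }
                )
    table = pd.DataFrame(rows)
    if return_draws:
        return table, all_draws
    return table
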