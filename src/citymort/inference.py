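"""Multilevel inference on posterior life-expectancy draws.

Three tools:

* ``decompose_variance`` — three-level variance decomposition of the
  life-expectancy draw panel (draws within cities within countries),
  LE_ijk = a000 + u_00k + u_0jk + e_ijk with normal random intercepts;
  reports the variance components (tau_country, tau_city, sigma2_draw)
  and the share of total variance at each level.  Estimation is a
  method-of-moments nested ANOVA (optionally weighted by baseline city
  population at the draw level); a restricted-likelihood fit from
  standard mixed-model machinery serves as a cross-check in the tests.
* ``icc_country`` — two-level intraclass correlation (between-country
  share of variance) for city-level quantities such as cause-specific
  proportionate mortality.
* ``le_association`` — draw-wise linear mixed models (random intercept
  for country) of life expectancy on scaled city predictors, with the
  per-draw coefficients pooled by Rubin's rules:
  Qbar = mean estimate, Wbar = mean within variance, B = between-draw
  variance of estimates, T = Wbar + (1 + 1/m) B, and a normal 95% CI.
  No p-values are reported.

``reshape_for_cause_model`` prepares the long cause-by-city table (cause
indicators, exposure interactions, log population offset with model-side
coverage weighting) consumed by a negative-binomial multilevel model;
the fit itself is delegated to standard mixed-model software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ages import CAUSE_GROUPS

REFERENCE_CAUSE = "CVD_NCD"


@dataclass(frozen=True)
class VarianceComponents:
    """Nested variance components and their shares of the total."""

    sigma2_draw: float
    tau_city: float
    tau_country: float
    single_country: bool = False

    @property
    def total(self) -> float:
        return self.sigma2_draw + self.tau_city + self.tau_country

    @property
    def proportions(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            return {"draw": 0.0, "city": 0.0, "country": 0.0}
        return {
            "draw": self.sigma2_draw / t,
            "city": self.tau_city / t,
            "country": self.tau_country / t,
        }


def _weighted_var(x: np.ndarray, w: np.ndarray) -> float:
    """Unbiased weighted variance (reliability weights)."""
    w = w / w.sum()
    m = np.sum(w * x)
    v = np.sum(w * (x - m) ** 2)
    denom = 1.0 - np.sum(w**2)
    return float(v / denom) if denom > 0 else 0.0


def decompose_variance(
    panel: pd.DataFrame,
    value_col: str = "life_expectancy",
    weight_col: str | None = "weight",
) -> VarianceComponents:
    """Method-of-moments three-level decomposition of a draw panel.

    ``panel`` columns: iteration, city_id, country_id, the value column
    and optionally a per-city weight (baseline population).  Draw counts
    must be balanced across cities.  With a single country the country
    component is reported as zero and flagged.
    """
    counts = panel.groupby("city_id")["iteration"].count()
    if counts.nunique() != 1:
        raise ValueError("draw panel must be balanced across cities")
    m = int(counts.iloc[0])

    grp = panel.groupby(["country_id", "city_id"])[value_col]
    city = grp.mean().rename("mean").to_frame()
    city["var"] = grp.var(ddof=1)
    city = city.reset_index()
    if weight_col and weight_col in panel.columns:
        w = (panel.groupby(["country_id", "city_id"])[weight_col].first()
             .reset_index(drop=True).to_numpy(dtype=float))
    else:
        w = np.ones(len(city))
    w = w / w.mean()

    # draw-level variance: weighted pool of within-city draw variances
    sigma2 = float(np.average(city["var"].to_numpy(), weights=w)) if m > 1 else 0.0

    # city level: variance of city means within country, minus the
    # sampling variance sigma^2/m of a city mean
    tau_city_terms = []
    country_means = []
    country_sizes = []
    for _, sub in city.groupby("country_id"):
        means = sub["mean"].to_numpy()
        wi = w[sub.index.to_numpy()]
        country_means.append(float(np.average(means, weights=wi)))
        country_sizes.append(len(means))
        if len(means) >= 2:
            tau_city_terms.append(_weighted_var(means, wi))
    if tau_city_terms:
        tau_city = max(0.0, float(np.mean(tau_city_terms)) - sigma2 / m)
    else:
        tau_city = 0.0

    # country level: variance of country means minus their sampling noise
    single_country = len(country_means) < 2
    if single_country:
        tau_country = 0.0
    else:
        cm = np.array(country_means)
        between = float(np.var(cm, ddof=1))
        correction = float(np.mean([
            tau_city / j + sigma2 / (j * m) for j in country_sizes
        ]))
        tau_country = max(0.0, between - correction)

    return VarianceComponents(
        sigma2_draw=sigma2, tau_city=tau_city, tau_country=tau_country,
        single_country=single_country,
    )


def icc_country(
    values: pd.DataFrame, value_col: str = "value"
) -> float:
    """Two-level ICC: between-country share of the variance of a
    city-level quantity (one row per city; columns country_id, value).

    One-way random-effects ANOVA estimator with the unbalanced-design
    n0 correction; clamped to [0, 1].
    """
    groups = [sub[value_col].to_numpy(dtype=float)
              for _, sub in values.groupby("country_id")]
    k = len(groups)
    if k < 2:
        return 0.0
    n_i = np.array([g.size for g in groups], dtype=float)
    N = n_i.sum()
    gm = np.concatenate(groups).mean()
    ssb = float(np.sum(n_i * (np.array([g.mean() for g in groups]) - gm) ** 2))
    ssw = float(np.sum([np.sum((g - g.mean()) ** 2) for g in groups]))
    msb = ssb / (k - 1)
    msw = ssw / (N - k) if N > k else 0.0
    n0 = (N - np.sum(n_i**2) / N) / (k - 1)
    tau = max(0.0, (msb - msw) / n0)
    denom = tau + msw
    return float(tau / denom) if denom > 0 else 0.0


@dataclass(frozen=True)
class PooledCoefficient:
    """A draw-wise coefficient pooled by Rubin's rules."""

    predictor: str
    estimate: float   # Qbar
    within: float     # Wbar
    between: float    # B
    m: int

    @property
    def total_variance(self) -> float:
        return self.within + (1.0 + 1.0 / self.m) * self.between

    @property
    def ci95(self) -> tuple[float, float]:
        half = 1.959963984540054 * np.sqrt(self.total_variance)
        return (self.estimate - half, self.estimate + half)


def pool_rubin(estimates: np.ndarray, variances: np.ndarray,
               predictor: str = "") -> PooledCoefficient:
    """Rubin's rules for m repeated analyses of posterior draws."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.size != u.size or q.size < 1:
        raise ValueError("estimates and variances must align, m >= 1")
    m = q.size
    qbar = float(q.mean())
    wbar = float(u.mean())
    b = float(q.var(ddof=1)) if m > 1 else 0.0
    return PooledCoefficient(predictor=predictor, estimate=qbar,
                             within=wbar, between=b, m=m)


@dataclass
class ModelSpec:
    """Outcome/predictor layout for the draw-wise mixed models."""

    predictors: list
    covariates: list = field(default_factory=list)

    @property
    def terms(self) -> list:
        return list(self.predictors) + list(self.covariates)


def random_intercept_gls(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, n_iter: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Random-intercept linear model by moments + generalized least squares.

    Variance components are estimated from the residual one-way ANOVA
    (between/within the grouping factor), then coefficients and their
    covariance come from GLS with V = sigma2*I + tau*ZZ', inverted in
    closed form per group.  Always defined (tau clamps at 0, where the
    fit reduces to OLS), which is what the draw-wise pooling needs: no
    optimizer, no convergence failures.

    Returns (beta, cov_beta).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    codes, _ = pd.factorize(groups)
    G = codes.max() + 1
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    for _ in range(n_iter):
        resid = y - X @ beta
        n_g = np.bincount(codes).astype(float)
        means = np.bincount(codes, weights=resid) / n_g
        ssw = float(np.sum((resid - means[codes]) ** 2))
        N = y.size
        sigma2 = ssw / max(N - G, 1)
        if G >= 2:
            gm = resid.mean()
            msb = float(np.sum(n_g * (means - gm) ** 2)) / (G - 1)
            n0 = (N - np.sum(n_g**2) / N) / (G - 1)
            tau = max(0.0, (msb - sigma2) / n0)
        else:
            tau = 0.0
        sigma2 = max(sigma2, 1e-12)
        # GLS via the Woodbury identity, group by group
        XtVX = np.zeros((X.shape[1], X.shape[1]))
        XtVy = np.zeros(X.shape[1])
        for g in range(G):
            idx = codes == g
            Xg, yg = X[idx], y[idx]
            k = tau / (sigma2 + n_g[g] * tau) if tau > 0 else 0.0
            xs, ys_ = Xg.sum(axis=0), yg.sum()
            XtVX += (Xg.T @ Xg - k * np.outer(xs, xs)) / sigma2
            XtVy += (Xg.T @ yg - k * xs * ys_) / sigma2
        cov = np.linalg.pinv(XtVX)
        beta = cov @ XtVy
    return beta, cov


def le_association(
    panel: pd.DataFrame,
    predictors: pd.DataFrame,
    spec: ModelSpec,
    value_col: str = "life_expectancy",
    max_failed_frac: float = 0.05,
    backend: str = "mom",
) -> list[PooledCoefficient]:
    """Linear mixed model of life expectancy on city predictors, fitted
    once per posterior draw and pooled by Rubin's rules.

    ``panel``: (iteration, city_id, country_id, value); ``predictors``:
    one row per city, already scaled (see profiles.scale_predictors).
    A random intercept for country is included in every fit.  The default
    backend is the closed-form moments+GLS fit; ``backend="reml"`` uses
    restricted-likelihood mixed-model machinery instead, where draws
    whose fit fails to converge are skipped (more than 5% skipped is an
    error).
    """
    df = panel.merge(predictors, on="city_id", how="left", validate="m:1")
    if df[spec.terms].isna().any().any():
        raise ValueError("missing predictor values after merge")
    iterations = np.sort(df["iteration"].unique())
    m = iterations.size

    names = spec.terms
    ests = {p: [] for p in names}
    vars_ = {p: [] for p in names}
    failed = 0
    for it in iterations:
        sub = df[df.iteration == it]
        X = sub[names].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(sub)), X])
        ygrp = sub[value_col].to_numpy(dtype=float)
        groups = sub["country_id"].to_numpy()
        if backend == "mom":
            beta, cov = random_intercept_gls(ygrp, X, groups)
            fe, var_fe = beta, np.diag(cov)
        elif backend == "reml":
            from statsmodels.regression.mixed_linear_model import MixedLM

            fit = None
            for method in ("lbfgs", "powell"):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        cand = MixedLM(ygrp, X, groups=groups).fit(
                            reml=True, method=method)
                    if np.all(np.isfinite(cand.bse_fe[1:])):
                        fit = cand
                        break
                except Exception:
                    continue
            if fit is None:
                failed += 1
                continue
            fe, var_fe = fit.fe_params, fit.bse_fe**2
        else:
            raise ValueError(f"unknown backend {backend!r}")
        for i, p in enumerate(names):
            ests[p].append(fe[i + 1])
            vars_[p].append(var_fe[i + 1])
    if failed > max_failed_frac * m:
        raise RuntimeError(f"{failed}/{m} draw-wise fits failed to converge")
    if failed:
        warnings.warn(f"{failed}/{m} draw-wise fits skipped", stacklevel=2)
    return [pool_rubin(np.array(ests[p]), np.array(vars_[p]), predictor=p)
            for p in names]


def reshape_for_cause_model(
    deaths_by_cause: pd.DataFrame,
    predictors: pd.DataFrame,
    population: pd.DataFrame,
    coverage: pd.DataFrame | None = None,
    exposure_cols: tuple[str, ...] = (),
    reference: str = REFERENCE_CAUSE,
) -> pd.DataFrame:
    """Long cause x city table for the aggregated count model.

    One row per (cause, city): death counts, four cause indicator
    columns (reference cause all-zero), optional exposure-by-cause
    interaction columns, and an ``offset`` equal to log of the
    coverage-weighted population (model-side correction: population
    multiplied by coverage).  Estimation of the negative-binomial mixed
    model itself is delegated to standard software.
    """
    d = (deaths_by_cause.groupby(["country_id", "city_id", "cause_group"])
         ["deaths"].sum().reset_index())
    pop = population.groupby("city_id")["population"].sum().rename("population")
    base = d.join(pop, on="city_id")
    if coverage is not None:
        cov = (coverage.drop_duplicates("city_id").set_index("city_id")["phi"])
        base["coverage"] = base["city_id"].map(cov).fillna(1.0)
    else:
        base["coverage"] = 1.0
    base["offset"] = np.log(base["population"] * base["coverage"])

    others = [c for c in CAUSE_GROUPS if c != reference]
    for c in others:
        base[f"cause_{c}"] = (base.cause_group == c).astype(float)
    base = base.merge(predictors, on="city_id", how="left",
                      suffixes=("", "_pred"))
    for expo in exposure_cols:
        for c in others:
            base[f"{expo}_x_{c}"] = base[expo] * base[f"cause_{c}"]
    return base
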