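"""Hierarchical Bayesian Poisson model for city/age/sex mortality rates.

Deaths y in city j (country i), age group k, sex s are modelled as

    y ~ Poisson(c * n * lambda),     log lambda = beta0_ks + alpha_is + z_jks

where n is person-years of exposure, c in (0, 1] is the city/sex
registration-completeness factor, beta0_ks is an age/sex intercept,
alpha_is a country-level random effect shrunk toward zero
(alpha ~ N(0, tau_s^2)), and z_jks a city-level deviation that evolves
across age groups as an AR(1) process

    z_1 ~ N(0, sigma_1s^2),   z_k ~ N(rho_s * z_{k-1}, sigma_ks^2)

so each city may bend away from its country's age pattern, but only
smoothly.  Registration uncertainty enters through the moment-matched
completeness prior c ~ Beta(K*phi, K*(1-phi)); the model's job is not to
learn c but to propagate its uncertainty into the rates.

Sexes are modelled independently (every parameter is sex-specific).
Sampling is an adaptive Metropolis-within-Gibbs scheme: vectorized
random-walk updates for beta0, alpha, z (odd/even age interleave), c
(logit scale), tau and sigma (log scale), and a conjugate truncated-normal
Gibbs draw for rho.  Proposal scales adapt toward 44% acceptance during
burn-in only, so the retained chain is a valid fixed-kernel sample.

Hyperpriors (weakly informative): beta0 ~ N(0, 10^2), tau ~ half-N(0,1),
sigma_k ~ half-N(0,1), rho ~ U(0,1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .ages import AGE_GROUPS, N_AGE, SEXES

_TARGET_ACC = 0.44


@dataclass
class ModelConfig:
    """MCMC schedule and sampler settings.

    The default schedule (50,000 burn-in, 100,000 iterations, thin 100)
    retains 1,000 draws; tests and small panels use a scaled-down
    schedule through the same interface.
    """

    burn_in: int = 50_000
    iterations: int = 100_000
    thin: int = 100
    seed: int = 0
    beta0_sd: float = 10.0
    adapt_interval: int = 50
    fix_coverage: bool = False  # force c = 1 (no undercount correction)

    def __post_init__(self):
        if min(self.burn_in, self.iterations, self.thin) <= 0:
            raise ValueError("burn_in, iterations and thin must be positive")
        if self.iterations % self.thin:
            raise ValueError("iterations must be a multiple of thin")

    @property
    def retained(self) -> int:
        return self.iterations // self.thin


@dataclass
class ModelData:
    """Aggregated inputs: deaths, exposures and completeness priors.

    Arrays are indexed (city, age, sex) with cities sorted canonically by
    (country_id, city_id) so results do not depend on input row order.
    Cells with zero exposure are masked out of the likelihood; a masked
    city/sex still receives posterior draws (prior-driven).
    """

    y: np.ndarray            # (J, 17, S) observed death counts
    n: np.ndarray            # (J, 17, S) person-years
    country_idx: np.ndarray  # (J,) index into country_ids
    city_ids: list
    country_ids: list
    sexes: list = field(default_factory=lambda: list(SEXES))
    prior_alpha: np.ndarray | None = None  # (J, S) Beta shape a, NaN -> c fixed 1
    prior_beta: np.ndarray | None = None   # (J, S) Beta shape b

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        J, K, S = self.y.shape
        if K != N_AGE or self.n.shape != self.y.shape:
            raise ValueError("y and n must both be (n_city, 17, n_sex)")
        if np.any(self.y < 0) or np.any(self.y != np.floor(self.y)):
            raise ValueError("deaths must be non-negative integers")
        if np.any((self.n <= 0) & (self.y > 0)):
            raise ValueError("positive deaths require positive exposure")
        if self.prior_alpha is None:
            self.prior_alpha = np.full((J, S), np.nan)
            self.prior_beta = np.full((J, S), np.nan)

    @property
    def mask(self) -> np.ndarray:
        return self.n > 0


def model_data_from_frames(
    deaths: pd.DataFrame,
    population: pd.DataFrame,
    completeness: pd.DataFrame | None = None,
    person_years_mode: str = "geometric",
) -> ModelData:
    """Assemble ModelData from the flat CSV schemas.

    ``deaths``: preprocessed table (no missing sex/age), aggregated here
    over year and cause.  ``population``: two time points per city/sex on
    the 17-group grid.  ``completeness``: ensemble output with one
    (alpha, beta) pair per city and sex; omit to fix c = 1.
    """
    times = np.sort(population["time"].unique())
    if times.size != 2:
        raise ValueError("population must contain exactly two time points")
    t1, t2 = times
    T = t2 - t1

    cities = (population[["country_id", "city_id"]].drop_duplicates()
              .sort_values(["country_id", "city_id"]).reset_index(drop=True))
    city_ids = cities.city_id.tolist()
    country_ids = sorted(cities.country_id.unique())
    c_lookup = {c: i for i, c in enumerate(country_ids)}
    country_idx = np.array([c_lookup[c] for c in cities.country_id])

    J, S = len(city_ids), len(SEXES)
    y = np.zeros((J, N_AGE, S))
    n = np.zeros((J, N_AGE, S))
    agg = deaths.groupby(["city_id", "sex", "age_group"])["deaths"].sum()
    pop = population.set_index(["city_id", "sex", "age_group", "time"])["population"]
    for j, city in enumerate(city_ids):
        for s, sex in enumerate(SEXES):
            for k, age in enumerate(AGE_GROUPS):
                y[j, k, s] = agg.get((city, sex, age), 0.0)
                n1 = pop.get((city, sex, age, t1), 0.0)
                n2 = pop.get((city, sex, age, t2), 0.0)
                if person_years_mode == "geometric":
                    n[j, k, s] = T * np.sqrt(n1 * n2)
                elif person_years_mode == "arithmetic":
                    n[j, k, s] = T * (n1 + n2) / 2.0
                else:
                    raise ValueError(f"unknown mode {person_years_mode!r}")

    pa = np.full((J, S), np.nan)
    pb = np.full((J, S), np.nan)
    if completeness is not None:
        pri = (completeness[["city_id", "sex", "alpha", "beta"]]
               .drop_duplicates(["city_id", "sex"])
               .set_index(["city_id", "sex"]))
        for j, city in enumerate(city_ids):
            for s, sex in enumerate(SEXES):
                if (city, sex) in pri.index:
                    pa[j, s] = pri.loc[(city, sex), "alpha"]
                    pb[j, s] = pri.loc[(city, sex), "beta"]
    return ModelData(y=y, n=n, country_idx=country_idx, city_ids=city_ids,
                     country_ids=country_ids, prior_alpha=pa, prior_beta=pb)


def _sample_one_sex(
    y: np.ndarray,           # (J, K)
    n: np.ndarray,           # (J, K)
    mask: np.ndarray,        # (J, K)
    country_idx: np.ndarray, # (J,)
    prior_a: np.ndarray,     # (J,) NaN -> c fixed at 1
    prior_b: np.ndarray,
    cfg: ModelConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    from scipy.special import ndtr, ndtri

    J, K = y.shape
    C = int(country_idx.max()) + 1 if J else 1
    n_safe = np.where(mask, n, 1.0)
    ym = y * mask

    free_c = (~np.isnan(prior_a)) & (~cfg.fix_coverage)
    pa = np.where(free_c, prior_a, 1.0)
    pb = np.where(free_c, prior_b, 1.0)

    # --- state ---
    c = np.where(free_c, np.clip(pa / (pa + pb), 0.02, 0.995), 1.0)
    with np.errstate(divide="ignore"):
        beta0 = np.log((ym.sum(axis=0) + 0.5) /
                       np.maximum((c[:, None] * n_safe * mask).sum(axis=0), 1e-9))
    alpha = np.zeros(C)
    z = np.zeros((J, K))
    tau, rho = 0.3, 0.5
    sigma = np.full(K, 0.3)

    # --- adaptive proposal scales (log) ---
    ls = {
        "beta0": np.full(K, np.log(0.05)),
        "alpha": np.full(C, np.log(0.05)),
        "z": np.full((J, K), np.log(0.1)),
        "c": np.full(J, np.log(0.2)),
        "tau": np.log(0.3),
        "sigma": np.full(K, np.log(0.3)),
        # likelihood-invariant recentering moves (see below)
        "swap_beta0": np.log(0.05),
        "swap_alpha": np.full(C, np.log(0.1)),
        "swap_c": np.full(J, np.log(0.1)),
        "swap_level": np.log(0.1),
    }
    acc = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in ls.items()}

    country_mat = np.zeros((J, C))
    country_mat[np.arange(J), country_idx] = 1.0

    def lam():
        return np.exp(beta0[None, :] + alpha[country_idx][:, None] + z)

    mu = c[:, None] * n_safe * lam() * mask
    Yk = ym.sum(axis=0)                 # per age group
    Yi = country_mat.T @ ym.sum(axis=1) # per country
    Yj = ym.sum(axis=1)                 # per city

    even_k = np.arange(0, K, 2)
    odd_k = np.arange(1, K, 2)

    retained = cfg.retained
    out = {
        "lam": np.empty((retained, J, K)),
        "c": np.empty((retained, J)),
        "beta0": np.empty((retained, K)),
        "alpha": np.empty((retained, C)),
        "z": np.empty((retained, J, K)),
        "tau": np.empty(retained),
        "rho": np.empty(retained),
        "sigma": np.empty((retained, K)),
    }

    total = cfg.burn_in + cfg.iterations
    r_idx = 0
    for t in range(total):
        # ---- beta0 (vector over k) ----
        delta = rng.normal(0.0, np.exp(ls["beta0"]))
        dll = (Yk * delta - mu.sum(axis=0) * np.expm1(delta)
               + (beta0**2 - (beta0 + delta) ** 2) / (2 * cfg.beta0_sd**2))
        accept = np.log(rng.uniform(size=K)) < dll
        beta0 = np.where(accept, beta0 + delta, beta0)
        mu[:, accept] *= np.exp(delta[accept])[None, :]
        acc["beta0"] += accept

        # ---- alpha (vector over country) ----
        delta = rng.normal(0.0, np.exp(ls["alpha"]))
        Mi = country_mat.T @ mu.sum(axis=1)
        dll = (Yi * delta - Mi * np.expm1(delta)
               + (alpha**2 - (alpha + delta) ** 2) / (2 * tau**2))
        accept = np.log(rng.uniform(size=C)) < dll
        alpha = np.where(accept, alpha + delta, alpha)
        row_scale = np.exp(np.where(accept, delta, 0.0))[country_idx]
        mu *= row_scale[:, None]
        acc["alpha"] += accept

        # ---- z (odd/even interleave, vectorized over cities) ----
        for cols in (even_k, odd_k):
            delta = rng.normal(0.0, np.exp(ls["z"][:, cols]))
            znew = z[:, cols] + delta
            dll = ym[:, cols] * delta - mu[:, cols] * np.expm1(delta)
            # own AR term
            prev = np.where(cols[None, :] > 0, rho * z[:, np.maximum(cols - 1, 0)], 0.0)
            s_own = sigma[cols][None, :]
            dll += ((z[:, cols] - prev) ** 2 - (znew - prev) ** 2) / (2 * s_own**2)
            # successor AR term
            has_next = cols < K - 1
            nxt = np.minimum(cols + 1, K - 1)
            s_nxt = sigma[nxt][None, :]
            resid_old = z[:, nxt] - rho * z[:, cols]
            resid_new = z[:, nxt] - rho * znew
            dll += np.where(has_next[None, :],
                            (resid_old**2 - resid_new**2) / (2 * s_nxt**2), 0.0)
            accept = np.log(rng.uniform(size=dll.shape)) < dll
            z[:, cols] = np.where(accept, znew, z[:, cols])
            mu[:, cols] *= np.exp(np.where(accept, delta, 0.0))
            acc["z"][:, cols] += accept

        # ---- c (logit scale, vector over cities) ----
        if free_c.any():
            Tj = (mu / c[:, None]).sum(axis=1)  # sum_k n*lam*mask
            logit = np.log(c) - np.log1p(-c)
            prop = logit + rng.normal(0.0, np.exp(ls["c"]))
            cnew = 1.0 / (1.0 + np.exp(-prop))
            dll = ((pa + Yj) * (np.log(cnew) - np.log(c))
                   + pb * (np.log1p(-cnew) - np.log1p(-c))
                   - (cnew - c) * Tj)
            accept = free_c & (np.log(rng.uniform(size=J)) < dll)
            ratio = np.where(accept, cnew / c, 1.0)
            c = np.where(accept, cnew, c)
            mu *= ratio[:, None]
            acc["c"] += accept

        # ---- recentering moves ----
        # The likelihood only identifies sums like beta0 + alpha + z and
        # products like c * lambda; these deterministic swap moves travel
        # along those flat directions (likelihood unchanged, only priors
        # enter the ratio), which is what makes beta0/alpha/c mix.

        # (a) beta0_k += delta_k, z_.k -= delta_k  (joint over all k)
        delta = rng.normal(0.0, np.exp(ls["swap_beta0"]), size=K)
        e = np.empty(K)
        e[0] = delta[0]
        e[1:] = delta[1:] - rho * delta[:-1]
        resid = np.empty((J, K))
        resid[:, 0] = z[:, 0]
        resid[:, 1:] = z[:, 1:] - rho * z[:, :-1]
        dlp = np.sum((2.0 * resid.sum(axis=0) * e - J * e**2) / (2 * sigma**2))
        dlp += np.sum(beta0**2 - (beta0 + delta) ** 2) / (2 * cfg.beta0_sd**2)
        if np.log(rng.uniform()) < dlp:
            beta0 = beta0 + delta
            z = z - delta[None, :]
            acc["swap_beta0"] += 1

        # (b) alpha_i += delta_i, z_jk -= delta_i for cities in country i
        delta = rng.normal(0.0, np.exp(ls["swap_alpha"]))
        g = np.full(K, 1.0 - rho)
        g[0] = 1.0
        resid[:, 0] = z[:, 0]
        resid[:, 1:] = z[:, 1:] - rho * z[:, :-1]
        rg = (resid * (g / sigma**2)[None, :]).sum(axis=1)   # per city
        g2 = np.sum(g**2 / sigma**2)
        per_city = 2.0 * rg[:, None] * delta[None, :] - g2 * delta[None, :] ** 2
        dlp = (country_mat * per_city).sum(axis=0) / 2.0
        dlp += (alpha**2 - (alpha + delta) ** 2) / (2 * tau**2)
        accept = np.log(rng.uniform(size=C)) < dlp
        alpha = np.where(accept, alpha + delta, alpha)
        z = z - np.where(accept, delta, 0.0)[country_idx][:, None]
        acc["swap_alpha"] += accept

        # (d) beta0 += delta (all k), alpha -= delta (all countries):
        # the common-level flat direction between intercepts and country
        # effects; only the two normal priors enter
        delta = float(rng.normal(0.0, np.exp(ls["swap_level"])))
        dlp = (np.sum(beta0**2 - (beta0 + delta) ** 2) / (2 * cfg.beta0_sd**2)
               + np.sum(alpha**2 - (alpha - delta) ** 2) / (2 * tau**2))
        if np.log(rng.uniform()) < dlp:
            beta0 = beta0 + delta
            alpha = alpha - delta
            acc["swap_level"] += 1

        # (c) log c_j += delta_j, z_j. -= delta_j  (c * lambda preserved)
        if free_c.any():
            delta = rng.normal(0.0, np.exp(ls["swap_c"]))
            cnew = c * np.exp(delta)
            ok = free_c & (cnew < 1.0)
            resid[:, 0] = z[:, 0]
            resid[:, 1:] = z[:, 1:] - rho * z[:, :-1]
            rg = (resid * (g / sigma**2)[None, :]).sum(axis=1)
            dlp = (2.0 * rg * delta - g2 * delta**2) / 2.0
            dlp += pa * delta + (pb - 1.0) * (np.log1p(-np.where(ok, cnew, 0.5))
                                              - np.log1p(-c))
            accept = ok & (np.log(rng.uniform(size=J)) < dlp)
            c = np.where(accept, cnew, c)
            z = z - np.where(accept, delta, 0.0)[:, None]
            acc["swap_c"] += accept

        # ---- tau (log scale) ----
        prop = np.log(tau) + rng.normal(0.0, np.exp(ls["tau"]))
        tnew = np.exp(prop)
        a2 = np.sum(alpha**2)
        dll = (-(C - 1) * (np.log(tnew) - np.log(tau))
               - a2 / 2 * (1 / tnew**2 - 1 / tau**2)
               - (tnew**2 - tau**2) / 2)
        if np.log(rng.uniform()) < dll:
            tau = tnew
            acc["tau"] += 1

        # ---- sigma (vector over k) ----
        resid = np.empty((J, K))
        resid[:, 0] = z[:, 0]
        resid[:, 1:] = z[:, 1:] - rho * z[:, :-1]
        r2 = (resid**2).sum(axis=0)
        prop = np.log(sigma) + rng.normal(0.0, np.exp(ls["sigma"]))
        snew = np.exp(prop)
        dll = (-(J - 1) * (prop - np.log(sigma))
               - r2 / 2 * (1 / snew**2 - 1 / sigma**2)
               - (snew**2 - sigma**2) / 2)
        accept = np.log(rng.uniform(size=K)) < dll
        sigma = np.where(accept, snew, sigma)
        acc["sigma"] += accept

        # ---- rho (conjugate truncated-normal Gibbs, inverse-CDF draw) ----
        w = 1.0 / sigma[1:] ** 2
        den = np.sum((z[:, :-1] ** 2) * w[None, :])
        if den > 0:
            num = np.sum(z[:, 1:] * z[:, :-1] * w[None, :])
            m, sd = num / den, 1.0 / np.sqrt(den)
            pa_, pb_ = ndtr((0.0 - m) / sd), ndtr((1.0 - m) / sd)
            u = rng.uniform(pa_, pb_)
            rho = float(np.clip(m + sd * ndtri(u), 1e-12, 1 - 1e-12))
        else:
            rho = float(rng.uniform())

        # ---- adapt proposals during burn-in ----
        if t < cfg.burn_in and (t + 1) % cfg.adapt_interval == 0:
            step = min(0.25, 5.0 / np.sqrt(t + 1.0))
            for key in ls:
                rate = acc[key] / cfg.adapt_interval
                ls[key] = ls[key] + step * (rate - _TARGET_ACC)
            acc = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in ls.items()}

        if t >= cfg.burn_in and (t - cfg.burn_in) % cfg.thin == cfg.thin - 1:
            out["lam"][r_idx] = lam()
            out["c"][r_idx] = c
            out["beta0"][r_idx] = beta0
            out["alpha"][r_idx] = alpha
            out["z"][r_idx] = z
            out["tau"][r_idx] = tau
            out["rho"][r_idx] = rho
            out["sigma"][r_idx] = sigma
            r_idx += 1
    return out


def _diagnostics(posterior: xr.Dataset, n_lambda_cells: int = 24) -> pd.DataFrame:
    """Split-R-hat and effective sample size for the age/sex intercepts
    and a systematic sample of mortality-rate cells."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az

    def _split(chain: np.ndarray) -> np.ndarray:
        # fold one chain into two half-chains so R-hat is the split version
        half = chain.size // 2
        return chain[: 2 * half].reshape(2, half)

    rows = []
    b = posterior["beta0"].values  # (draw, age, sex)
    for s in range(b.shape[2]):
        for k in range(b.shape[1]):
            ida = az.convert_to_dataset(_split(b[:, k, s]))
            rows.append(dict(param=f"beta0[{AGE_GROUPS[k]},{posterior.sex.values[s]}]",
                             rhat=float(az.rhat(ida)["x"]),
                             ess=float(az.ess(ida)["x"])))
    lam = posterior["lam"].values  # (draw, city, age, sex)
    _, J, K, S = lam.shape
    flat = [(j, k, s) for j in range(J) for k in range(K) for s in range(S)]
    stride = max(1, len(flat) // n_lambda_cells)
    for j, k, s in flat[::stride][:n_lambda_cells]:
        ida = az.convert_to_dataset(_split(lam[:, j, k, s]))
        rows.append(dict(param=f"lam[{j},{k},{s}]",
                         rhat=float(az.rhat(ida)["x"]),
                         ess=float(az.ess(ida)["x"])))
    return pd.DataFrame(rows)


def fit_mortality_model(data: ModelData, config: ModelConfig) -> xr.Dataset:
    """Fit the model and return retained posterior draws.

    Returns an xarray Dataset with named dimensions (draw, city, age,
    sex, country): variables lam, c, beta0, alpha, z, tau, rho, sigma,
    plus convergence diagnostics in ``attrs``.  A warning is raised when
    more than 5% of monitored parameters have split-R-hat above 1.1.
    """
    J, K, S = data.y.shape
    results = []
    for s in range(S):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(s,)))
        results.append(
            _sample_one_sex(
                data.y[:, :, s], data.n[:, :, s], data.mask[:, :, s],
                data.country_idx, data.prior_alpha[:, s], data.prior_beta[:, s],
                config, rng,
            )
        )

    def stack(key):
        return np.stack([r[key] for r in results], axis=-1)

    coords = dict(
        draw=np.arange(config.retained),
        city=data.city_ids,
        age=list(AGE_GROUPS),
        sex=list(data.sexes),
        country=data.country_ids,
    )
    posterior = xr.Dataset(
        dict(
            lam=(("draw", "city", "age", "sex"), stack("lam")),
            z=(("draw", "city", "age", "sex"), stack("z")),
            c=(("draw", "city", "sex"), stack("c")),
            beta0=(("draw", "age", "sex"), stack("beta0")),
            alpha=(("draw", "country", "sex"), stack("alpha")),
            tau=(("draw", "sex"), stack("tau")),
            rho=(("draw", "sex"), stack("rho")),
            sigma=(("draw", "age", "sex"), stack("sigma")),
        ),
        coords=coords,
        attrs=dict(
            burn_in=config.burn_in, iterations=config.iterations,
            thin=config.thin, seed=config.seed,
        ),
    )
    posterior = posterior.assign_coords(
        city_country=("city", [data.country_ids[i] for i in data.country_idx])
    )

    diag = _diagnostics(posterior)
    bad = (diag.rhat > 1.1).mean()
    posterior.attrs["max_rhat"] = float(diag.rhat.max())
    posterior.attrs["frac_rhat_above_1p1"] = float(bad)
    posterior.attrs["min_ess"] = float(diag.ess.min())
    if bad > 0.05:
        warnings.warn(
            f"possible non-convergence: {bad:.0%} of monitored parameters "
            f"have split-R-hat > 1.1 (max {diag.rhat.max():.3f})",
            stacklevel=2,
        )
    return posterior


def posterior_rate_summaries(posterior: xr.Dataset) -> pd.DataFrame:
    """Equal-tailed posterior summaries (2.5/50/97.5 percentiles) of the
    mortality rate for every (city, age, sex) cell."""
    lam = posterior["lam"]
    qs = lam.quantile([0.025, 0.5, 0.975], dim="draw")
    df = qs.to_dataset(dim="quantile").to_dataframe().reset_index()
    df = df.rename(columns={0.025: "lo95", 0.5: "median", 0.975: "hi95"})
    country = dict(zip(posterior.city.values, posterior.city_country.values))
    df["country_id"] = df["city"].map(country)
    return df[["country_id", "city", "age", "sex", "lo95", "median", "hi95"]].rename(
        columns={"city": "city_id", "age": "age_group"}
    )
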