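"""Staged pipeline: simulate -> preprocess -> completeness -> fit ->
life tables -> profiles -> inference.

Every stage reads and writes flat CSV files in one output directory (the
posterior is a self-describing netCDF array); a JSON manifest records
the configuration, derived seeds, row counts and SHA-256 checksums of
every output.  Re-running with the same configuration reproduces every
stage bit-for-bit (the MCMC stage given the same seed).  A stage runs
when any of its outputs is missing or any upstream stage ran in the same
invocation, so deleting one output regenerates only that stage and its
descendants.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import bayes, completeness, inference, lifetables, preprocess, profiles, synthetic

STAGES = ("simulate", "preprocess", "completeness", "fit",
          "lifetables", "profiles", "infer")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    outdir: str | Path = "citymort_run"
    seed: int = 0
    # synthetic-panel settings (ignored when input paths are given)
    synthetic: bool = True
    n_countries: int = 2
    cities_per_country: int = 5
    mean_population: float = 300_000.0
    deaths_path: str | None = None
    population_path: str | None = None
    # MCMC schedule
    burn_in: int = 50_000
    iterations: int = 100_000
    thin: int = 100
    # inference settings
    association_draws: int = 200
    stages: tuple = STAGES
    force: bool = False

    def small(self) -> "RunConfig":
        """Scaled-down schedule for smoke tests and small panels."""
        self.burn_in, self.iterations, self.thin = 2_000, 4_000, 4
        self.association_draws = 50
        return self


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    # stable per-stage seed derived from the master seed
    ss = np.random.SeedSequence(master, spawn_key=(STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2**31))


class Pipeline:
    """Executes the stage DAG over one output directory."""

    OUTPUTS = {
        "simulate": ["deaths.csv", "deaths_true.csv", "population.csv", "truth.json"],
        "preprocess": ["deaths_clean.csv", "ill_defined_summary.csv"],
        "completeness": ["completeness.csv"],
        "fit": ["posterior.nc"],
        "lifetables": ["life_expectancy.csv", "life_expectancy_draws.csv"],
        "profiles": ["profiles.csv"],
        "infer": ["variance_components.csv", "associations.csv"],
    }

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"config": {k: str(v) if isinstance(v, Path) else v
                                          for k, v in asdict(config).items()},
                               "stages": {}}

    # ---- stage implementations ----

    def stage_simulate(self):
        cfg = self.cfg
        if not cfg.synthetic:
            # external inputs: copy through so downstream paths are uniform
            for src, dst in ((cfg.deaths_path, "deaths.csv"),
                             (cfg.population_path, "population.csv")):
                if src is None:
                    raise ValueError("non-synthetic runs need input paths")
                (self.outdir / dst).write_bytes(Path(src).read_bytes())
            (self.outdir / "deaths_true.csv").write_text("")
            (self.outdir / "truth.json").write_text("{}")
            return
        truths = synthetic.make_panel_truths(
            cfg.n_countries, cfg.cities_per_country,
            seed=_stage_seed(cfg.seed, "simulate"),
            mean_population=cfg.mean_population,
        )
        panel = synthetic.simulate_deaths(truths, seed=_stage_seed(cfg.seed, "simulate"))
        synthetic.write_panel(panel, self.outdir)

    def stage_preprocess(self):
        deaths = pd.read_csv(self.outdir / "deaths.csv")
        summary = preprocess.summarize_ill_defined(deaths)
        clean = preprocess.preprocess(deaths, seed=_stage_seed(self.cfg.seed, "preprocess"))
        clean.to_csv(self.outdir / "deaths_clean.csv", index=False)
        summary.to_csv(self.outdir / "ill_defined_summary.csv", index=False)

    def stage_completeness(self):
        deaths = pd.read_csv(self.outdir / "deaths_clean.csv")
        pop = pd.read_csv(self.outdir / "population.csv")
        table = completeness.completeness_table(pop, deaths)
        table.to_csv(self.outdir / "completeness.csv", index=False)

    def stage_fit(self):
        cfg = self.cfg
        deaths = pd.read_csv(self.outdir / "deaths_clean.csv")
        pop = pd.read_csv(self.outdir / "population.csv")
        comp = pd.read_csv(self.outdir / "completeness.csv")
        data = bayes.model_data_from_frames(deaths, pop, comp)
        mc = bayes.ModelConfig(burn_in=cfg.burn_in, iterations=cfg.iterations,
                               thin=cfg.thin, seed=_stage_seed(cfg.seed, "fit"))
        posterior = bayes.fit_mortality_model(data, mc)
        posterior.to_netcdf(self.outdir / "posterior.nc", engine="scipy")

    def stage_lifetables(self):
        posterior = xr.open_dataset(self.outdir / "posterior.nc", engine="scipy")
        lam = posterior["lam"].values
        city_ids = [str(c) for c in posterior.city.values]
        country_ids = [str(c) for c in posterior.city_country.values]
        sexes = [str(s) for s in posterior.sex.values]
        table, draws = lifetables.le_table(
            lam, city_ids, country_ids, sexes, return_draws=True
        )
        table.to_csv(self.outdir / "life_expectancy.csv", index=False)
        n_draws = draws.shape[0]
        long = []
        for j, city in enumerate(city_ids):
            for s, sex in enumerate(sexes):
                for r, age in enumerate(lifetables.REF_AGES):
                    long.append(pd.DataFrame(dict(
                        iteration=np.arange(n_draws), country_id=country_ids[j],
                        city_id=city, sex=sex, ref_age=age,
                        life_expectancy=draws[:, j, s, r],
                    )))
        pd.concat(long, ignore_index=True).to_csv(
            self.outdir / "life_expectancy_draws.csv", index=False)

    def stage_profiles(self):
        deaths = pd.read_csv(self.outdir / "deaths_clean.csv")
        pop = pd.read_csv(self.outdir / "population.csv")
        comp_path = self.outdir / "completeness.csv"
        cov = pd.read_csv(comp_path)[["city_id", "sex", "phi"]] if comp_path.exists() else None
        table = profiles.profile_table(deaths, pop, coverage=cov)
        table.to_csv(self.outdir / "profiles.csv", index=False)

    def stage_infer(self):
        draws = pd.read_csv(self.outdir / "life_expectancy_draws.csv")
        pop = pd.read_csv(self.outdir / "population.csv")
        base = (pop[pop.time == pop.time.min()]
                .groupby(["country_id", "city_id"])["population"].sum()
                .rename("weight").reset_index())

        rows = []
        for (sex, age), sub in draws.groupby(["sex", "ref_age"]):
            panel = sub.merge(base[["city_id", "weight"]], on="city_id")
            vc = inference.decompose_variance(panel)
            props = vc.proportions
            rows.append(dict(sex=sex, ref_age=age,
                             sigma2_draw=vc.sigma2_draw, tau_city=vc.tau_city,
                             tau_country=vc.tau_country,
                             prop_draw=props["draw"], prop_city=props["city"],
                             prop_country=props["country"]))
        pd.DataFrame(rows).to_csv(self.outdir / "variance_components.csv", index=False)

        # draw-wise associations of e0 with city size and growth
        t1, t2 = np.sort(pop.time.unique())
        p1 = pop[pop.time == t1].groupby("city_id")["population"].sum()
        p2 = pop[pop.time == t2].groupby("city_id")["population"].sum()
        pred = pd.DataFrame({
            "city_id": p1.index,
            "population": p1.to_numpy(),
            "growth": profiles.city_growth(p1.to_numpy(), p2.to_numpy()),
        })
        pred, _ = profiles.scale_predictors(pred, log_columns=("population",))
        out = []
        for (sex, age), sub in draws.groupby(["sex", "ref_age"]):
            m = self.cfg.association_draws
            keep = sub[sub.iteration < m]
            for term in ("population", "growth"):
                coefs = inference.le_association(
                    keep.rename(columns={"life_expectancy": "life_expectancy"}),
                    pred[["city_id", term]],
                    inference.ModelSpec(predictors=[term]),
                )
                pc = coefs[0]
                lo, hi = pc.ci95
                out.append(dict(sex=sex, ref_age=age, predictor=term,
                                estimate=pc.estimate, lo95=lo, hi95=hi, m_used=pc.m))
        pd.DataFrame(out).to_csv(self.outdir / "associations.csv", index=False)

    # ---- DAG driver ----

    def run(self) -> dict:
        upstream_ran = False
        for stage in STAGES:
            if stage not in self.cfg.stages:
                continue
            outputs = [self.outdir / f for f in self.OUTPUTS[stage]]
            need = (self.cfg.force or upstream_ran
                    or not all(p.exists() for p in outputs))
            entry = {"ran": bool(need), "outputs": {}}
            if need:
                t0 = time.time()
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    getattr(self, f"stage_{stage}")()
                entry["seconds"] = round(time.time() - t0, 2)
                entry["warnings"] = sorted({str(w.message) for w in caught})
                upstream_ran = True
            for p in outputs:
                if p.exists() and p.stat().st_size:
                    info = {"sha256": _sha256(p)}
                    if p.suffix == ".csv":
                        info["rows"] = max(0, sum(1 for _ in p.open()) - 1)
                    entry["outputs"][p.name] = info
            self.manifest["stages"][stage] = entry
        manifest_path = self.outdir / "manifest.json"
        manifest_path.write_text(json.dumps(self.manifest, indent=1))
        return self.manifest


def run_pipeline(config: RunConfig) -> dict:
    """Run (or resume) the pipeline; returns the manifest."""
    return Pipeline(config).run()
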