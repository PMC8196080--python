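"""End-to-end pipeline: simulate -> stockflow -> metrics -> geo -> maps.

Each stage reads and writes format-stable files (long CSV tables, ESRI ASCII
rasters, YAML config) so stages can be rerun independently. One master seed
derives a fixed per-stage seed, making the whole run reproducible: identical
config + seed give identical output hashes for the deterministic stages and
identical posterior summaries for the sampling stages.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics, synth, transforms
from .gp import fit_gp
from .rasters import write_ascii_grid, grid_coords
from .stockflow import (CountryInputs, MCMCSettings, fit_stock_and_flow,
                        survey_crop_estimate)
from .surfaces import compose_maps, relative_gain, uncertainty_classify, exceedance

STAGES = ("simulate", "stockflow", "metrics", "geo", "maps", "relative_gain")


@dataclass
class RunConfig:
    out_dir: str = "run"
    master_seed: int = 0
    stages: tuple = STAGES
    synthetic: synth.SyntheticConfig | None = None
    survey_years: tuple = (2006, 2010, 2014, 2018)
    survey_month: int = 6
    mcmc: MCMCSettings | None = None
    n_draws: int = 100
    target_year: int = 2017
    exceedance_threshold: float = 0.5

    def __post_init__(self) -> None:
        order = [STAGES.index(s) for s in self.stages]
        if order != sorted(order) or order != list(range(len(order))):
            raise ValueError("stages must form a prefix of the pipeline DAG")

    def stage_seed(self, stage: str) -> int:
        return (self.master_seed * 10007 + zlib.crc32(stage.encode())) % 2 ** 31


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_inputs(paths: dict) -> list[str]:
    """Schema checks on the pipeline's CSV inputs. Returns violation strings
    with row numbers; empty list means well-formed."""
    issues = []
    for key in ("deliveries", "distributions"):
        if key not in paths:
            continue
        df = pd.read_csv(paths[key])
        need = {"country", "year", "net_type", "count"}
        if not need.issubset(df.columns):
            issues.append(f"{key}: missing columns {sorted(need - set(df.columns))}")
            continue
        for i in df.index[df["count"] < 0]:
            issues.append(f"{key} row {i}: negative count {df.loc[i, 'count']}")
    if "survey" in paths:
        df = pd.read_csv(paths["survey"])
        need = set(metrics.SURVEY_COLUMNS)
        if not need.issubset(df.columns):
            issues.append(f"survey: missing columns {sorted(need - set(df.columns))}")
        else:
            bad = df.index[df["sleepers_under_nets"] > df["defacto_size"]]
            for i in bad:
                issues.append(f"survey row {i}: sleepers exceed de facto size")
            for i in df.index[df["defacto_size"] < 1]:
                issues.append(f"survey row {i}: de facto size < 1")
            for col in ("n_citn", "n_llin"):
                for i in df.index[df[col] < 0]:
                    issues.append(f"survey row {i}: negative {col}")
    return issues


def run_pipeline(config: RunConfig, return_state: bool = False):
    """Execute the enabled stage prefix and return the run manifest
    (and, when ``return_state`` is set, the in-memory stage state)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.master_seed, "stages": {}, "files": {}}
    state: dict = {}
    for stage in config.stages:
        t0 = time.time()
        try:
            _STAGE_FUNCS[stage](config, state, out)
        except Exception:
            manifest["stages"][stage] = {"status": "failed"}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise
        manifest["stages"][stage] = {
            "status": "ok",
            "seed": config.stage_seed(stage),
            "wall_clock_s": round(time.time() - t0, 3),
        }
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return (manifest, state) if return_state else manifest


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, state: dict, out: Path) -> None:
    scfg = config.synthetic or synth.SyntheticConfig(seed=config.stage_seed("simulate"))
    world = synth.build_world(scfg)
    state["world"] = world
    scfg.to_yaml(out / "synthetic_config.yaml")
    deliv = pd.concat([cw.deliveries for cw in world.countries.values()])
    dist = pd.concat([cw.distributions for cw in world.countries.values()])
    deliv.to_csv(out / "deliveries.csv", index=False)
    dist.to_csv(out / "distributions.csv", index=False)
    surveys = []
    for cid in world.countries:
        for year in config.survey_years:
            surveys.append(synth.generate_survey(world, cid, year, config.survey_month))
    survey = pd.concat(surveys, ignore_index=True)
    survey.to_csv(out / "survey.csv", index=False)
    state["survey"] = survey
    for cid, cw in world.countries.items():
        write_ascii_grid(out / f"population_{cid}.asc", cw.population_raster)
        write_ascii_grid(out / f"covariate_{cid}.asc", cw.covariate)
    issues = validate_inputs({"deliveries": out / "deliveries.csv",
                              "distributions": out / "distributions.csv",
                              "survey": out / "survey.csv"})
    if issues:
        raise RuntimeError(f"simulated inputs failed validation: {issues[:5]}")


def _stage_stockflow(config: RunConfig, state: dict, out: Path) -> None:
    world = state["world"]
    mcmc = config.mcmc or MCMCSettings()
    mcmc.seed = config.stage_seed("stockflow")
    fits = {}
    summaries = []
    mean_hh = float(np.arange(1, 16) @ world.config.household_size_pmf)
    for cid, cw in world.countries.items():
        n_households = cw.population / mean_hh
        surveys = []
        for year in config.survey_years:
            sub = state["survey"][state["survey"]["survey_id"]
                                  == f"{cid}-{year}-{config.survey_month:02d}"]
            est, se = survey_crop_estimate(sub, n_households)
            q = world.quarter_of(year, config.survey_month)
            surveys.append((q, est, se))
        deliveries = _quarterly_deliveries(cw, world.config)
        reported = {
            t: cw.distributions.query("net_type == @t")["count"].to_numpy(float)
            for t in ("llin", "citn")
        }
        inputs = CountryInputs(
            deliveries=deliveries, reported=reported,
            population=np.full(world.config.n_years, cw.population),
            surveys=surveys)
        fit = fit_stock_and_flow(inputs, k_steepness=world.config.loss_k,
                                 settings=mcmc)
        fits[cid] = fit
        s = fit.summary.copy()
        s.insert(0, "country", cid)
        summaries.append(s)
    state["stockflow"] = fits
    pd.concat(summaries).to_csv(out / "stockflow_summary.csv", index=False)
    tau_rows = [{"country": cid, "net_type": t,
                 "tau_median": float(np.median(f.tau[t])),
                 "tau_lo": float(np.quantile(f.tau[t], 0.025)),
                 "tau_hi": float(np.quantile(f.tau[t], 0.975))}
                for cid, f in fits.items() for t in f.tau]
    pd.DataFrame(tau_rows).to_csv(out / "retention_times.csv", index=False)


def _quarterly_deliveries(cw, scfg) -> dict:
    # quarterly delivery timing (campaign arrival quarters) is treated as
    # known, as campaign schedules are in practice
    return {t: cw.true_deliveries_q[t].copy() for t in ("llin", "citn")}


def _national_series(config: RunConfig, state: dict) -> dict:
    """Monthly national access/npc tables per country from the stock-and-flow
    posterior plus the crop-to-access calibration learned from the survey."""
    world = state["world"]
    out = {}
    for cid, fit in state["stockflow"].items():
        agg = state["aggregates"][cid] if "aggregates" in state else None
        if agg is None or len(agg) < 5:
            raise RuntimeError("metrics stage must run before national series")
        _, curve = metrics.crop_to_access(
            agg["npc"].to_numpy(), agg["npc"].to_numpy(), agg["access"].to_numpy())
        rows = []
        npc_mean = fit.summary["npc_mean"].to_numpy()
        for y in range(world.config.n_years):
            for m in range(1, 13):
                q = 4 * y + (m - 1) // 3
                rows.append({"year": world.config.year_start + y, "month": m,
                             "npc": npc_mean[q],
                             "access": float(curve(npc_mean[q]))})
        out[cid] = {"table": pd.DataFrame(rows), "curve": curve}
    return out


def _stage_metrics(config: RunConfig, state: dict, out: Path) -> None:
    world = state["world"]
    state["aggregates"] = {}
    for cid in world.countries:
        sub = state["survey"][state["survey"]["survey_id"].str.startswith(cid + "-")]
        state["aggregates"][cid] = metrics.cluster_aggregates(sub)
    state["national"] = _national_series(config, state)
    tables = []
    for cid, agg in state["aggregates"].items():
        dev = metrics.deviation_metrics(agg, state["national"][cid]["table"])
        dev.insert(0, "country", cid)
        state["aggregates"][cid] = dev
        tables.append(dev)
    pd.concat(tables, ignore_index=True).to_csv(out / "cluster_aggregates.csv",
                                                index=False)


_METRIC_SPECS = [("access_deviation", True), ("use_gap_signed", True),
                 ("npc_deviation", False)]


def _stage_geo(config: RunConfig, state: dict, out: Path) -> None:
    world = state["world"]
    rng = np.random.default_rng(config.stage_seed("geo"))
    eps = 1e-3
    target_q = world.quarter_of(config.target_year, config.survey_month)
    target_month = ((config.target_year - world.config.year_start) * 12
                    + config.survey_month - 1)
    state["geo"] = {}
    for cid, dev in state["aggregates"].items():
        cw = world.countries[cid]
        coords = dev[["lat", "lon"]].to_numpy(float)
        months = ((dev["year"] - world.config.year_start) * 12
                  + dev["month"] - 1).to_numpy(float)
        covar_obs = cw.covariate[coords[:, 0].astype(int), coords[:, 1].astype(int)]
        X = np.column_stack([np.ones(len(dev)), covar_obs])
        grid = grid_coords(world.config.grid_shape)
        Xg = np.column_stack([np.ones(grid.shape[0]), cw.covariate.ravel()])
        tg = np.full(grid.shape[0], target_month, dtype=float)
        draws = {}
        for name, bounded in _METRIC_SPECS:
            y = transforms.forward_chain(
                np.clip(dev[name].to_numpy(float), -1 if bounded else -np.inf, 1),
                bounded, eps)
            # tiny coordinate jitter: two clusters can share a pixel-month
            jitter = 1e-6 * rng.standard_normal(coords.shape)
            model = fit_gp(coords + jitter, months, y, X)
            _, d = model.predict(grid, tg, Xg, n_draws=config.n_draws, rng=rng)
            back = transforms.inverse_chain(d, bounded, eps)
            draws[name] = back.reshape(config.n_draws, *world.config.grid_shape)
        state["geo"][cid] = {"draws": draws, "target_q": target_q,
                             "target_month": target_month}


def _stage_maps(config: RunConfig, state: dict, out: Path) -> None:
    world = state["world"]
    rng = np.random.default_rng(config.stage_seed("maps") + 1)
    state["maps"] = {}
    for cid, geo in state["geo"].items():
        cw = world.countries[cid]
        fit = state["stockflow"][cid]
        q = geo["target_q"]
        idx = rng.integers(fit.npc.shape[0], size=config.n_draws)
        npc_draws = fit.npc[idx, q]
        curve = state["national"][cid]["curve"]
        access_draws = np.asarray(curve(npc_draws), float)
        composed = compose_maps(
            {"access": access_draws, "npc": npc_draws},
            geo["draws"], cw.mask, time_index=q)
        state["maps"][cid] = composed
        rows = []
        for name in ("access", "use", "use_rate", "npc"):
            cr = composed[name]
            for suffix, arr in (("mean", cr.mean), ("lo", cr.lo), ("hi", cr.hi)):
                write_ascii_grid(out / f"{name}_{suffix}_{cid}.asc", arr)
            flat = pd.DataFrame({
                "country": cid, "metric": name, "quarter": q,
                "cell": np.arange(cr.mean.size),
                "mean": cr.mean.ravel(), "lo": cr.lo.ravel(), "hi": cr.hi.ravel(),
            })
            rows.append(flat)
        pd.concat(rows).to_csv(out / f"map_summary_{cid}.csv", index=False)
        classes = uncertainty_classify(
            composed["access"].mean, composed["access"].hi - composed["access"].lo,
            cw.population_raster, cw.mask)
        write_ascii_grid(out / f"access_uncertainty_class_{cid}.asc",
                         classes.astype(float))
        exc = exceedance(composed["access_draws"], config.exceedance_threshold,
                         cw.mask)
        write_ascii_grid(out / f"access_exceedance_{cid}.asc", exc)


def _stage_relative_gain(config: RunConfig, state: dict, out: Path) -> None:
    for cid, composed in state["maps"].items():
        g_rate, g_access = relative_gain(composed["access"].mean,
                                         composed["use"].mean)
        write_ascii_grid(out / f"gain_from_use_rate_{cid}.asc", g_rate)
        write_ascii_grid(out / f"gain_from_access_{cid}.asc", g_access)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "stockflow": _stage_stockflow,
    "metrics": _stage_metrics,
    "geo": _stage_geo,
    "maps": _stage_maps,
    "relative_gain": _stage_relative_gain,
}
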