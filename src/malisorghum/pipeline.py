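"""End-to-end pipeline: synthetic weather -> simulation -> envirotyping.

A single configuration (sites with isohyet zones and rainfall targets,
soils, cultivars, a seed, an output directory) drives the whole study:
weather is generated per site-season, every site-year x soil x cultivar
combination is simulated, daily supply/demand records are reduced to
trajectories, the trajectories are clustered jointly into drought scenarios,
seasons are weighted so isohyets compare fairly, and scenario-frequency and
yield-distribution tables are written as CSV.  Fully reproducible from the
config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import envirotyping as env
from .canopy import ManagementSpec
from .evaluation import build_manifest
from .phenology import CULTIVAR_PRESETS, cultivar_preset
from .simulate import simulate_season
from .soil import SOIL_PRESETS, soil_preset
from .weather import SiteSpec, generate_season

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config",
           "demo_sites"]

log = logging.getLogger("malisorghum")

#: A scaled-down site roster spanning the north-south rainfall gradient: two
#: stations per isohyet zone with their observed latitudes and long-term mean
#: annual rainfalls (mm).
DEMO_SITE_TABLE = (
    ("Nara", 15.2, "400-600", 426.0),
    ("Mopti", 14.5, "400-600", 492.0),
    ("Segou", 13.4, "600-800", 661.0),
    ("Kolokani", 13.6, "600-800", 753.0),
    ("Samanko", 12.5, "800-1000", 920.0),
    ("Kita", 13.1, "800-1000", 986.0),
    ("Kangaba", 11.9, ">1000", 1040.0),
    ("Sikasso", 11.4, ">1000", 1170.0),
)


def demo_sites(n_seasons: int = 20) -> tuple:
    """Eight representative sites (two per isohyet zone), ``n_seasons`` each."""
    return tuple(
        SiteSpec(name=name, latitude=lat, isohyet_zone=zone,
                 target_annual_rainfall=rain, n_seasons=n_seasons)
        for name, lat, zone, rain in DEMO_SITE_TABLE
    )


@dataclass(frozen=True)
class PipelineConfig:
    sites: tuple  # of SiteSpec
    soils: tuple = ("low_swhc", "high_swhc")
    cultivars: tuple = ("CSM63E", "CSM335")
    seed: int = 1
    k_scenarios: int = 3
    cluster_method: str = "kmeans"
    output_dir: str | None = None
    management: ManagementSpec = field(default_factory=ManagementSpec)

    def __post_init__(self) -> None:
        for c in self.cultivars:
            if c not in CULTIVAR_PRESETS:
                raise ValueError(
                    f"unknown cultivar {c!r}; expected one of "
                    f"{sorted(CULTIVAR_PRESETS)}")
        for s in self.soils:
            if s not in SOIL_PRESETS:
                raise ValueError(
                    f"unknown soil {s!r}; expected one of {sorted(SOIL_PRESETS)}")


def load_config(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML/JSON key-value file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    sites = tuple(
        SiteSpec(name=s["name"], latitude=s["latitude"],
                 isohyet_zone=s["isohyet_zone"],
                 target_annual_rainfall=s["target_annual_rainfall"],
                 n_seasons=s.get("n_seasons", 1))
        for s in raw["sites"]
    )
    return PipelineConfig(
        sites=sites,
        soils=tuple(raw.get("soils", ("low_swhc", "high_swhc"))),
        cultivars=tuple(raw.get("cultivars", ("CSM63E", "CSM335"))),
        seed=int(raw.get("seed", 1)),
        k_scenarios=int(raw.get("k_scenarios", 3)),
        cluster_method=raw.get("cluster_method", "kmeans"),
        output_dir=raw.get("output_dir"),
    )


@dataclass
class PipelineResult:
    config: PipelineConfig
    results: list  # SeasonResult per completed run
    trajectories: list  # SDTrajectory per clusterable run
    excluded: list  # (run_id, reason)
    assignment: env.ScenarioAssignment
    weighting: env.WeightingSpec
    frequencies: pd.DataFrame
    summaries: pd.DataFrame

    def scenario_of(self) -> pd.DataFrame:
        rows = []
        for traj, scen in zip(self.trajectories, self.assignment.scenarios):
            site, year, soil, cultivar = traj.run_id
            rows.append({"site": site, "year": year, "soil": soil,
                         "cultivar": cultivar, "isohyet": traj.isohyet,
                         "scenario": scen,
                         "grain_yield_kg_ha": traj.grain_yield,
                         "biomass_kg_ha": traj.biomass_yield,
                         "weight": env.season_weight(self.weighting, traj.isohyet)})
        return pd.DataFrame(rows)


def simulate_runs(config: PipelineConfig):
    """Generate weather and simulate every run in the manifest."""
    manifest = build_manifest(
        [s.name for s in config.sites],
        [s.n_seasons for s in config.sites],
        config.soils, config.cultivars, seed=config.seed)
    sites = {s.name: s for s in config.sites}
    weather_cache: dict[tuple, object] = {}
    results, excluded = [], []
    for site_name, year, soil_name, cultivar_name in manifest.runs:
        key = (site_name, year)
        wx = weather_cache.get(key)
        if wx is None:
            wx = generate_season(sites[site_name], seed=config.seed, year=year)
            weather_cache[key] = wx
        res = simulate_season(wx, soil_preset(soil_name),
                              cultivar_preset(cultivar_name),
                              config.management)
        if not res.completed:
            excluded.append((res_id(res), "crop did not reach maturity"))
            continue
        results.append(res)
    return results, excluded


def res_id(res) -> tuple:
    return (res.site, res.year, res.soil, res.cultivar)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute synth -> simulate -> envirotype -> summarise.

    Runs that fail (crop failure, insufficient thermal span around
    flowering) are excluded from clustering with a logged reason; the
    pipeline continues.
    """
    results, excluded = simulate_runs(config)
    zones = {s.name: s.isohyet_zone for s in config.sites}

    trajectories = []
    for res in results:
        try:
            fidx = int(np.flatnonzero(res.doy == res.flowering_doy)[0])
            traj = env.extract_trajectory(
                res.daily_sd, res.daily_tt, fidx, run_id=res_id(res),
                grain_yield=res.crop.grain_yield_kg_ha,
                biomass_yield=res.crop.biomass_kg_ha,
                isohyet=zones[res.site])
        except env.TrajectoryExclusionError as exc:
            excluded.append((res_id(res), str(exc)))
            continue
        trajectories.append(traj)
    for run, reason in excluded:
        log.info("excluded %s: %s", run, reason)

    assignment = env.cluster_scenarios(
        trajectories, k=config.k_scenarios, method=config.cluster_method,
        seed=config.seed)
    counts: dict[str, int] = {}
    for t in trajectories:
        counts[t.isohyet] = counts.get(t.isohyet, 0) + 1
    weighting = env.WeightingSpec(seasons_in_isohyet=counts)
    frequencies = env.frequency_table(assignment, weighting)
    summaries = pd.DataFrame([r.summary() for r in results])

    out = PipelineResult(config=config, results=results,
                         trajectories=trajectories, excluded=excluded,
                         assignment=assignment, weighting=weighting,
                         frequencies=frequencies, summaries=summaries)
    if config.output_dir:
        write_outputs(out, Path(config.output_dir))
    return out


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.summaries.to_csv(outdir / "season_summaries.csv", index=False)
    result.frequencies.to_csv(outdir / "scenario_frequencies.csv")
    per_run = result.scenario_of()
    per_run.to_csv(outdir / "run_scenarios.csv", index=False)
    pd.DataFrame(result.assignment.centroids,
                 index=list(result.assignment.scenario_names),
                 columns=[f"tt_{lo}_{lo+100}" for lo in range(-400, 400, 100)]
                 ).to_csv(outdir / "cluster_centroids.csv")
    # cumulative yield-probability curves per isohyet
    cpf_frames = []
    for iso, grp in per_run.groupby("isohyet"):
        for col in ("grain_yield_kg_ha", "biomass_kg_ha"):
            curve = env.yield_cpf(grp[col].to_numpy(), grp["weight"].to_numpy())
            curve.insert(0, "isohyet", iso)
            curve.insert(1, "variable", col)
            cpf_frames.append(curve)
    pd.concat(cpf_frames, ignore_index=True).to_csv(
        outdir / "yield_cpf.csv", index=False)
    meta = {
        "seed": result.config.seed,
        "n_runs": len(result.results) + len(result.excluded),
        "n_clustered": len(result.trajectories),
        "excluded": [
            {"run": list(map(str, run)), "reason": reason}
            for run, reason in result.excluded
        ],
        "season_weights": {
            iso: env.season_weight(result.weighting, iso)
            for iso in result.weighting.seasons_in_isohyet
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(meta, indent=2))
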