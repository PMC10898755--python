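"""End-to-end analysis pipeline: simulate (or load) -> fit per element x year
-> predict over the grid -> decadal-change summaries -> files.

Outputs per element: posterior draw and summary CSVs for both years, a
convergence report, pointwise maps (per-year mean and 95% interval, percent
change, probability of decrease) as CSV + GeoJSON, and the stratum change
table.  A manifest records the configuration, all seeds and package versions
so a run is fully attributable.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import Observation, SiteRecord
from .inference import ConvergenceError, McmcConfig, PosteriorDrawSet, \
    convergence_diagnostics, fit_model
from .io import load_dataset, save_grid_csv, save_grid_geojson, save_observations
from .prediction import conditional_spatial_draws, pointwise_map_summaries, \
    predictive_concentration_draws
from .summaries import PairedYearDraws, paired_change_tables, pointwise_percent_change
from .synthetic import DesignConfig, GridConfig, GridPoint, default_truth, \
    generate_design, generate_prediction_grid, simulate_concentrations

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("roadmoss")


@dataclass
class PipelineConfig:
    """Everything a run needs; every random stage has its own recorded seed."""

    output_dir: str = "roadmoss_output"
    observations_path: str | None = None   # None -> simulate synthetic data
    grid_path: str | None = None           # None -> generate the default grid
    elements: tuple[str, ...] = ("Zn", "Pb", "Cd")
    years: tuple[int, int] = (2006, 2017)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    k_prediction_draws: int = 200
    include_new_site_effect: bool = True
    rhat_threshold: float = 1.05
    allow_nonconverged: bool = False
    design_seed: int = 11
    simulation_seed: int = 22
    prediction_seed: int = 33
    grid_seed: int = 44
    #: optional (element, year) -> ModelParameters overriding the default
    #: simulation truth (e.g. identical truth in both years for null-change
    #: calibration experiments)
    simulation_truths: dict | None = None

    def __post_init__(self) -> None:
        if len(self.years) != 2 or self.years[0] == self.years[1]:
            raise ValueError("years must be two distinct years")
        for e in self.elements:
            if e not in ("Zn", "Pb", "Cd"):
                raise ValueError(f"unknown element {e!r}")


@dataclass
class PipelineResult:
    output_dir: Path
    fits: dict
    diagnostics: dict
    change_tables: dict
    converged: bool


def _stage(name: str, outdir: Path):
    """Context manager: on failure, record the failed stage and re-raise."""
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            self.t0 = time.time()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                marker = outdir / "failed"
                marker.mkdir(parents=True, exist_ok=True)
                (marker / f"{name}.txt").write_text(f"stage {name} failed: {exc}\n")
                log.error("stage %s: FAILED (%s)", name, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, time.time() - self.t0)
    return _Ctx()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write all products under ``output_dir``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- data -------------------------------------------------------------
    with _stage("data", outdir):
        if config.observations_path is not None:
            sites, observations = load_dataset(config.observations_path)
        else:
            sites, plan = generate_design(DesignConfig(), seed=config.design_seed)
            observations = []
            rng = np.random.default_rng(config.simulation_seed)
            for element in config.elements:
                for year in config.years:
                    truth = (config.simulation_truths or {}).get(
                        (element, year)) or default_truth(element, year)
                    observations.extend(simulate_concentrations(
                        sites, plan, truth, element=element, year=year,
                        seed=int(rng.integers(2**31))))
            save_observations(outdir / "observations.csv", sites, observations)
        log.info("data: %d sites, %d observations", len(sites), len(observations))

    with _stage("grid", outdir):
        if config.grid_path is not None:
            from .io import load_grid_csv, load_grid_geojson
            p = str(config.grid_path)
            grid = load_grid_geojson(p) if p.endswith(".geojson") or p.endswith(".json") \
                else load_grid_csv(p)
        else:
            grid = generate_prediction_grid(GridConfig(), seed=config.grid_seed)
        save_grid_csv(outdir / "grid.csv", grid)
        save_grid_geojson(outdir / "grid.geojson", grid)

    fits: dict = {}
    diagnostics: dict = {}
    change_tables: dict = {}
    converged = True
    mcmc_seeds: dict = {}
    fit_rng = np.random.default_rng(config.mcmc.seed)

    for element in config.elements:
        # ---- fit per year -------------------------------------------------
        year_draws: dict[int, PosteriorDrawSet] = {}
        for year in config.years:
            with _stage(f"fit_{element}_{year}", outdir):
                obs = [o for o in observations
                       if o.element == element and o.year == year]
                mcmc = McmcConfig(**{**asdict(config.mcmc),
                                     "seed": int(fit_rng.integers(2**31))})
                mcmc_seeds[f"{element}_{year}"] = mcmc.seed
                drawset = fit_model(obs, sites, mcmc, element=element, year=year)
                year_draws[year] = drawset
                drawset.scalar_draws().to_csv(
                    outdir / f"draws_{element}_{year}.csv", index=False)
                drawset.summary().to_csv(
                    outdir / f"summary_{element}_{year}.csv", index=False)
                diag = convergence_diagnostics(drawset, config.rhat_threshold)
                diag.to_csv(outdir / f"diagnostics_{element}_{year}.csv", index=False)
                diagnostics[(element, year)] = diag
                if diag["flagged"].any():
                    converged = False
                    bad = diag.loc[diag["flagged"], "parameter"].tolist()
                    log.warning("fit %s %s: R-hat > %.2f for %s", element, year,
                                config.rhat_threshold, bad)
        fits[element] = year_draws

        # ---- predict ------------------------------------------------------
        with _stage(f"predict_{element}", outdir):
            pred_rng = np.random.default_rng(config.prediction_seed)
            predictive = {}
            for year in config.years:
                s_eta = int(pred_rng.integers(2**31))
                s_alpha = int(pred_rng.integers(2**31))
                eta_star = conditional_spatial_draws(
                    year_draws[year], sites, grid,
                    K=config.k_prediction_draws, seed=s_eta)
                predictive[year] = predictive_concentration_draws(
                    year_draws[year], grid, eta_star,
                    include_new_site_effect=config.include_new_site_effect,
                    seed=s_alpha)
                maps = pointwise_map_summaries(predictive[year])
                maps.to_csv(outdir / f"map_{element}_{year}.csv", index=False)
                save_grid_geojson(outdir / f"map_{element}_{year}.geojson", grid, maps)

        # ---- summarize ----------------------------------------------------
        with _stage(f"summarize_{element}", outdir):
            paired = PairedYearDraws(predictive[config.years[0]],
                                     predictive[config.years[1]])
            _, change_map = pointwise_percent_change(paired)
            change_map.to_csv(outdir / f"map_{element}_change.csv", index=False)
            save_grid_geojson(outdir / f"map_{element}_change.geojson", grid, change_map)
            table = paired_change_tables(paired, grid)
            table.to_csv(outdir / f"change_table_{element}.csv", index=False)
            change_tables[element] = table

    # ---- manifest ---------------------------------------------------------
    with _stage("manifest", outdir):
        config_dict = asdict(config)
        if config_dict.get("simulation_truths"):
            config_dict["simulation_truths"] = {
                f"{el}_{yr}": truth
                for (el, yr), truth in config_dict["simulation_truths"].items()}
        manifest = {
            "package": "roadmoss", "version": __version__,
            "numpy": np.__version__, "pandas": pd.__version__,
            "config": config_dict,
            "mcmc_seeds_per_fit": mcmc_seeds,
            "converged": converged,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    if not converged and not config.allow_nonconverged:
        raise ConvergenceError(
            "one or more fits have R-hat above the threshold; re-run with a "
            "longer schedule or allow_nonconverged=True")
    return PipelineResult(outdir, fits, diagnostics, change_tables, converged)
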