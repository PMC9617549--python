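"""End-to-end orchestration of the two-step zero-inflated BP pipeline.

Order of stages: grids/synthetic world -> occurrence SDMs (replicates,
ensembles, weighted consensus, cut-off) -> BP regression (cross-validated
random forest, per-cell prediction, hurdle mask) -> scenario reports
(BP_t, gain/loss, contributions, difference maps).

The pipeline is deterministic given (config, seed): one global seed fans out to
per-stage and per-species child seeds by stable hashing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import platform
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import bp as bp_index
from . import regression, scenarios, sdm, synth
from .grids import (
    EnvStack,
    GridSpec,
    Surface,
    read_env_stack,
    read_station_table,
    read_trait_table,
    station_cells,
    write_surface,
)
from .seeding import child_seed

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full configuration of one pipeline run; defaults follow the study design."""

    out_dir: str | None = None
    stations_path: str | None = None
    traits_path: str | None = None
    env_path: str | None = None
    species: list[str] | None = None
    years: list[int] = field(default_factory=lambda: list(synth.DEFAULT_YEARS))
    baseline_year: int = 2001
    algorithms: tuple[str, ...] = sdm.DEFAULT_ALGORITHMS
    algo_config: sdm.AlgorithmConfig = field(default_factory=sdm.AlgorithmConfig)
    n_reps: int = 20
    train_frac: float = 0.7
    auc_min: float = sdm.AUC_MIN_DEFAULT
    tss_min: float = sdm.TSS_MIN_DEFAULT
    weight_metric: str = "tss"
    lat_cut: float = 56.0
    seed: int = 0
    # synthetic-world settings, used when no input paths are given
    synthetic: bool = True
    grid: GridSpec = field(default_factory=lambda: synth.DEFAULT_GRID)
    warming: float = synth.DEFAULT_WARMING
    freshening: float = synth.DEFAULT_FRESHENING
    n_stations: int = synth.DEFAULT_N_STATIONS

    def __post_init__(self) -> None:
        if self.baseline_year not in self.years:
            raise ValueError("baseline year must be one of the scenario years")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must lie in (0, 1)")
        if not (0 <= self.auc_min <= 1 and -1 <= self.tss_min <= 1):
            raise ValueError("thresholds outside metric ranges")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "grid" in raw and isinstance(raw["grid"], dict):
            raw["grid"] = GridSpec(**raw["grid"])
        if "algo_config" in raw and isinstance(raw["algo_config"], dict):
            raw["algo_config"] = sdm.AlgorithmConfig(**raw["algo_config"])
        if "algorithms" in raw:
            raw["algorithms"] = tuple(raw["algorithms"])
        return cls(**raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = dataclasses.asdict(self.grid)
        d["algo_config"] = dataclasses.asdict(self.algo_config)
        d["algorithms"] = list(self.algorithms)
        return d


def warming_response_run(
    seed: int = 0, warming_total: float = 3.0, species: str = "coldclam", lat_cut: float = 54.0
) -> tuple["PipelineResult", dict]:
    """Two-year scenario run isolating one cold-optimum species under a uniform
    mean warming of `warming_total` degrees C by the final year.

    Returns the pipeline result plus a summary with the BP-weighted latitude
    centroid per year and the gain/loss of the species over the whole grid and
    the southern sub-region.  A species with its thermal optimum below the
    ambient mean should shift poleward: centroid up, southern loss at least as
    severe as the whole-grid change.  `lat_cut` bounds the "core" southern
    region; the default keeps the species' baseline core inside it while
    leaving the northernmost band as the expansion zone.
    """
    config = default_config(
        seed=seed,
        years=[2001, 2099],
        warming=warming_total,
        species=[species],
        lat_cut=lat_cut,
    )
    result = run_pipeline(config)
    sr = result.species_results[species]
    centroids = {year: scenarios.bp_weighted_latitude(sr.bp_masked[year]) for year in config.years}
    whole = result.gain_loss.set_index(["species", "year"])
    south = result.gain_loss_southern.set_index(["species", "year"])
    summary = {
        "centroid_baseline": centroids[2001],
        "centroid_final": centroids[2099],
        "gain_whole_pct": float(whole.loc[(species, 2099), "pct_change"]),
        "gain_south_pct": float(south.loc[(species, 2099), "pct_change"]),
    }
    return result, summary


def default_config(seed: int = 0, out_dir: str | None = None, **overrides) -> RunConfig:
    """Default synthetic-world run: 40 x 50 grid, 3 species, 284 stations,
    3 years, 20 replicates per algorithm.  lat_cut defaults to the middle of the
    synthetic grid so the southern region is a proper sub-region."""
    overrides.setdefault("lat_cut", 53.0)
    return RunConfig(seed=seed, out_dir=out_dir, **overrides)


@dataclass
class SpeciesResult:
    species: str
    mtry: int | None
    runs: list[sdm.ReplicateRun]
    consensus: dict[int, sdm.ConsensusSurface]
    cutoff: float
    regression_eval: regression.RegressionEvaluation
    bp_unmasked: dict[int, Surface]
    bp_masked: dict[int, Surface]


@dataclass
class PipelineResult:
    config: RunConfig
    env: EnvStack
    stations: pd.DataFrame
    traits: pd.DataFrame
    truth: synth.TruthBundle | None
    species_results: dict[str, SpeciesResult]
    excluded: list[str]
    bp_total: dict[int, Surface]
    sdm_eval: pd.DataFrame
    regression_eval: pd.DataFrame
    gain_loss: pd.DataFrame
    gain_loss_southern: pd.DataFrame
    contributions: pd.DataFrame
    difference_maps: dict[tuple[str, int], Surface]
    manifest: dict


# ---------------------------------------------------------------------------
# Stage 1: occurrence models


def fit_species_sdm(
    X: np.ndarray,
    y: np.ndarray,
    env: EnvStack,
    config: RunConfig,
    species: str,
    presence_scores: np.ndarray | None = None,
) -> tuple[int | None, list[sdm.ReplicateRun], dict[int, sdm.ConsensusSurface], float]:
    """Tune RF, fit all replicate runs, build per-year consensus and the cut-off.

    Returns (mtry, runs, consensus by year, cutoff).  Raises ValueError when no
    robust run survives the AUC/TSS filter.
    """
    mtry = None
    runs: list[sdm.ReplicateRun] = []
    algo_cfg = config.algo_config
    for algorithm in config.algorithms:
        cfg = algo_cfg
        if algorithm == "rf":
            mtry = sdm.tune_rf(
                X,
                y,
                mtry_candidates=algo_cfg.rf_mtry_candidates,
                config=algo_cfg,
                n_reps=config.n_reps,
                seed=child_seed(config.seed, "sdm", species),
                species=species,
            )
            cfg = dataclasses.replace(algo_cfg, rf_mtry=mtry)
        new_runs = sdm.fit_replicates(
            X,
            y,
            algorithm,
            cfg,
            n_reps=config.n_reps,
            train_frac=config.train_frac,
            seed=child_seed(config.seed, "sdm", species),
            species=species,
            auc_min=config.auc_min,
            tss_min=config.tss_min,
        )
        if not new_runs:
            log.warning("species %s: algorithm %s unavailable, skipped", species, algorithm)
            continue
        n_robust = sum(r.robust for r in new_runs)
        if n_robust == 0:
            log.warning("species %s: algorithm %s has no robust runs, dropped", species, algorithm)
        runs.extend(new_runs)

    cons = {
        year: sdm.consensus(runs, env, year, weight_metric=config.weight_metric)
        for year in config.years
    }
    base = cons[config.baseline_year]
    if presence_scores is None:
        raise ValueError("presence_scores (station cell indices) are required")
    scores = base.probability.values[presence_scores[:, 0], presence_scores[:, 1]]
    cutoff, _ = sdm.best_cutoff(scores, y)
    for year, c in cons.items():
        c.cutoff = cutoff
        c.binary = sdm.binarize(c.probability, cutoff)
    return mtry, runs, cons, cutoff


# ---------------------------------------------------------------------------
# Full pipeline


def run_pipeline(config: RunConfig) -> PipelineResult:
    logging.basicConfig(level=logging.INFO)
    if config.synthetic and config.stations_path is None:
        env, stations, traits, truth = synth.make_world(
            grid=config.grid,
            years=config.years,
            warming=config.warming,
            freshening=config.freshening,
            n_stations=config.n_stations,
            seed=config.seed,
        )
    else:
        env = read_env_stack(config.env_path, config.grid)
        stations = read_station_table(config.stations_path, grid=config.grid)
        traits = read_trait_table(config.traits_path)
        truth = None

    species_list = config.species or sorted(stations["species"].unique())
    cells = station_cells(stations, env)
    bp_station = bp_index.station_bp_table(stations, traits)

    species_results: dict[str, SpeciesResult] = {}
    excluded: list[str] = []
    sdm_rows, reg_rows = [], []

    for species in species_list:
        sub = stations[stations["species"] == species].set_index("station")
        cell_idx = cells.loc[sub.index, ["row", "col"]].to_numpy()
        X = env.predictor_matrix(config.baseline_year, cells=cell_idx)
        y = sub["presence"].to_numpy(dtype=int)
        try:
            n_folds = regression.choose_n_folds(int(y.sum()))
        except regression.UnmodellableSpeciesError as exc:
            log.warning("species %s excluded: %s", species, exc)
            excluded.append(species)
            continue
        try:
            mtry, runs, cons, cutoff = fit_species_sdm(
                X, y, env, config, species, presence_scores=cell_idx
            )
        except ValueError as exc:
            log.warning("species %s excluded at SDM stage: %s", species, exc)
            excluded.append(species)
            continue
        for r in runs:
            sdm_rows.append(
                {
                    "species": r.species,
                    "algorithm": r.algorithm,
                    "replicate": r.replicate,
                    "auc": round(r.auc, 6),
                    "tss": round(r.tss, 6),
                    "robust": int(r.robust),
                }
            )
        log.info(
            "species %s: %d/%d robust runs, mtry=%s, cutoff=%.3f",
            species,
            sum(r.robust for r in runs),
            len(runs),
            mtry,
            cutoff,
        )

        # step 2: BP regression
        table = regression.build_regression_table(
            bp_station, cells, env, cons[config.baseline_year].probability, species, config.baseline_year
        )
        reg_seed = child_seed(config.seed, "bp", species)
        ev = regression.cross_validate(table, n_folds, seed=reg_seed, species=species)
        model = regression.fit_bp_model(table, seed=reg_seed)
        ev.importance = regression.variable_importance(model, table, seed=reg_seed)
        reg_rows.append(
            {
                "species": species,
                "n_folds": n_folds,
                "mae": round(ev.mae, 6),
                "rmse": round(ev.rmse, 6),
                "mae_pct": round(ev.mae_pct, 4),
                "rmse_pct": round(ev.rmse_pct, 4),
                **{f"imp_{k}": round(v, 4) for k, v in ev.importance.items()},
            }
        )

        bp_unmasked, bp_masked = {}, {}
        for year in config.years:
            occ = cons[year].probability
            surf = regression.predict_bp_surface(model, env, occ, year)
            bp_unmasked[year] = surf
            bp_masked[year] = regression.zero_inflate_mask(surf, cons[year].binary)
        species_results[species] = SpeciesResult(
            species=species,
            mtry=mtry,
            runs=runs,
            consensus=cons,
            cutoff=cutoff,
            regression_eval=ev,
            bp_unmasked=bp_unmasked,
            bp_masked=bp_masked,
        )

    if not species_results:
        raise RuntimeError("no species could be modelled")

    # scenario aggregation
    bp_total = {
        year: bp_index.sum_bp_total([sr.bp_masked[year] for sr in species_results.values()], year)
        for year in config.years
    }
    surfaces = {
        (sp, year): sr.bp_masked[year] for sp, sr in species_results.items() for year in config.years
    }
    surfaces_with_total = dict(surfaces)
    for year, surf in bp_total.items():
        surfaces_with_total[("total", year)] = surf
    southern = scenarios.region_mask_southern(env.grid, config.lat_cut, land_mask=env.land_mask)
    gl = scenarios.gain_loss(surfaces_with_total, config.baseline_year)
    gl_south = scenarios.gain_loss(surfaces_with_total, config.baseline_year, region=southern)
    contrib_frames = []
    for year in config.years:
        try:
            contrib_frames.append(scenarios.relative_contribution(surfaces, year, region=southern))
        except ValueError as exc:  # zero regional BP_t: shares undefined for that year
            log.warning("contributions undefined for year %s: %s", year, exc)
            contrib_frames.append(
                pd.DataFrame(
                    {
                        "species": sorted(species_results),
                        "year": year,
                        "contribution_pct": np.nan,
                    }
                )
            )
    contributions = pd.concat(contrib_frames, ignore_index=True)
    diffs = {
        ("total", year): scenarios.difference_map(bp_total[config.baseline_year], bp_total[year])
        for year in config.years
        if year != config.baseline_year
    }

    manifest = {
        "config": config.echo(),
        "seed": config.seed,
        "python": platform.python_version(),
        "species_modelled": sorted(species_results),
        "species_excluded": excluded,
        "robust_runs": {
            sp: int(sum(r.robust for r in sr.runs)) for sp, sr in species_results.items()
        },
        "outputs": [],
    }

    result = PipelineResult(
        config=config,
        env=env,
        stations=stations,
        traits=traits,
        truth=truth,
        species_results=species_results,
        excluded=excluded,
        bp_total=bp_total,
        sdm_eval=pd.DataFrame(sdm_rows),
        regression_eval=pd.DataFrame(reg_rows),
        gain_loss=gl,
        gain_loss_southern=gl_south,
        contributions=contributions,
        difference_maps=diffs,
        manifest=manifest,
    )
    if config.out_dir:
        write_outputs(result, config.out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str) -> None:
    """Write surfaces, evaluation tables, reports and the run manifest."""
    os.makedirs(out_dir, exist_ok=True)
    surf_dir = os.path.join(out_dir, "surfaces")
    os.makedirs(surf_dir, exist_ok=True)
    outputs = []

    def save(surface: Surface, name: str) -> None:
        path = os.path.join(surf_dir, name)
        write_surface(surface, path)
        outputs.append(os.path.relpath(path, out_dir))

    for sp, sr in result.species_results.items():
        for year in result.config.years:
            cons = sr.consensus[year]
            save(cons.probability, f"prob_{sp}_{year}.nc")
            save(cons.binary, f"binary_{sp}_{year}.nc")
            save(sr.bp_masked[year], f"bp_{sp}_{year}.nc")
            save(sr.bp_unmasked[year], f"bp_unmasked_{sp}_{year}.nc")
    for year, surf in result.bp_total.items():
        save(surf, f"bp_total_{year}.nc")
    for (sp, year), surf in result.difference_maps.items():
        save(surf, f"diff_{sp}_{result.config.baseline_year}_{year}.nc")

    for name, frame in [
        ("sdm_evaluation.csv", result.sdm_eval),
        ("regression_evaluation.csv", result.regression_eval),
        ("gain_loss.csv", result.gain_loss),
        ("gain_loss_southern.csv", result.gain_loss_southern),
        ("contributions.csv", result.contributions),
    ]:
        path = os.path.join(out_dir, name)
        frame.to_csv(path, index=False, float_format="%.6f", na_rep="null")
        outputs.append(name)

    result.manifest["outputs"] = sorted(outputs)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)

    lines = [f"seed={result.config.seed} years={result.config.years} "
             f"algorithms={list(result.config.algorithms)}"]
    for sp, sr in result.species_results.items():
        n_robust = sum(r.robust for r in sr.runs)
        lines.append(
            f"species={sp} robust_runs={n_robust}/{len(sr.runs)} mtry={sr.mtry} "
            f"cutoff={sr.cutoff:.4f} n_folds={sr.regression_eval.n_folds} "
            f"mae={sr.regression_eval.mae:.4f} rmse={sr.regression_eval.rmse:.4f}"
        )
    for sp in result.excluded:
        lines.append(f"species={sp} excluded")
    with open(os.path.join(out_dir, "run.log"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
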