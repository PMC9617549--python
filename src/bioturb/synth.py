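"""Synthetic shelf-sea study system with known ground truth.

Builds a fully specified virtual world — an environmental stack with smooth
baseline fields and spatially smooth scenario deltas, virtual benthic species
with Gaussian niche responses, and a grab-survey station table — so every stage
of the two-step BP pipeline can be tested against known true occurrence
probabilities and true expected BP surfaces.

The default world mirrors the scale of a shelf-sea macrofauna survey where that
is cheap: 284 stations, three scenario years, a 40 x 50 cell grid, warming of a
few degrees per scenario step and a moderate freshening, and three virtual
species spanning cold-, warm- and broad-niche thermal responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import bp as bp_index
from .grids import ALL_LAYERS, DYNAMIC_LAYERS, STATIC_LAYERS, EnvStack, GridSpec, Surface
from .seeding import child_seed

#: default synthetic grid: 40 rows x 50 cols at 0.1 degree
DEFAULT_GRID = GridSpec(lon_min=2.0, lon_max=7.0, lat_min=51.0, lat_max=55.0, cell_size=0.1)
DEFAULT_YEARS = [2001, 2050, 2099]
#: spatial-mean warming per scenario step (deg C) and salinity decrease per step
DEFAULT_WARMING = 1.5
DEFAULT_FRESHENING = 0.85
DEFAULT_N_STATIONS = 284


@dataclass
class NicheParams:
    """Gaussian niche of one virtual species plus its survey/trait parameters.

    `responses` maps a layer name to (mu, sigma) in the layer's units; the true
    occurrence probability is max_prob times the product of the per-layer
    Gaussian terms.  Abundance given presence is a shifted negative binomial
    with mean lambda_max * probability and dispersion k.
    """

    species: str
    responses: dict[str, tuple[float, float]]
    max_prob: float = 0.9
    lambda_max: float = 60.0
    mean_ind_biomass: float = 0.5
    M: int = 3
    R: int = 3
    dispersion_k: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.max_prob <= 1:
            raise ValueError("max_prob must lie in (0, 1]")
        for layer, (_, sigma) in self.responses.items():
            if sigma <= 0:
                raise ValueError(f"sigma must be positive for layer {layer!r}")
            if layer not in ALL_LAYERS:
                raise ValueError(f"unknown niche layer {layer!r}")


@dataclass
class TruthBundle:
    """Ground truth of a synthetic world: probabilities, expected BP, survey."""

    prob: dict[tuple[str, int], Surface] = field(default_factory=dict)
    bp: dict[tuple[str, int], Surface] = field(default_factory=dict)
    stations: pd.DataFrame | None = None


def default_niches() -> list[NicheParams]:
    """Three virtual species: a cold-water, a warm-water and a broad generalist.

    The cold-niche species has its thermal optimum below the ambient June mean,
    so warming pushes its suitable habitat poleward — the qualitative pattern
    the projection stage must reproduce.
    """
    return [
        NicheParams(
            species="coldclam",
            responses={"temp_jun": (11.0, 1.5), "sal_jun": (34.5, 2.5), "depth": (65.0, 30.0), "mud": (40.0, 40.0)},
            max_prob=0.95,
            lambda_max=80.0,
            mean_ind_biomass=0.4,
            M=2,
            R=4,
            dispersion_k=5.0,
        ),
        NicheParams(
            species="warmworm",
            responses={"temp_jun": (16.5, 1.5), "sal_jun": (33.5, 3.0), "depth": (20.0, 25.0), "mud": (20.0, 40.0)},
            max_prob=0.9,
            lambda_max=50.0,
            mean_ind_biomass=0.8,
            M=3,
            R=3,
            dispersion_k=5.0,
        ),
        NicheParams(
            species="broadstar",
            responses={"temp_jun": (13.5, 1.5), "sal_jun": (34.0, 3.0), "depth": (45.0, 30.0), "mud": (30.0, 45.0)},
            max_prob=0.9,
            lambda_max=40.0,
            mean_ind_biomass=1.2,
            M=4,
            R=2,
            dispersion_k=5.0,
        ),
    ]


def trait_table(niches: list[NicheParams]) -> pd.DataFrame:
    return pd.DataFrame(
        {"species": [n.species for n in niches], "M": [n.M for n in niches], "R": [n.R for n in niches]}
    )


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator, sd: float, corr_cells: float = 6.0) -> np.ndarray:
    """Zero-mean spatially smooth Gaussian field with marginal SD ~ sd."""
    noise = rng.standard_normal(shape)
    smooth = gaussian_filter(noise, sigma=corr_cells, mode="reflect")
    s = smooth.std()
    if s == 0:
        return np.zeros(shape)
    return smooth * (sd / s)


def default_land_mask(grid: GridSpec) -> np.ndarray:
    """Deterministic coastal land block in the south-east corner (~8% of cells)."""
    lats = grid.lats[:, None]
    lons = grid.lons[None, :]
    coast = (lons - grid.lon_max + 0.8) + (grid.lat_min + 0.9 - lats)
    return coast > 0.6


def make_env_stack(
    grid: GridSpec = DEFAULT_GRID,
    years: list[int] = DEFAULT_YEARS,
    warming: float = DEFAULT_WARMING,
    freshening: float = DEFAULT_FRESHENING,
    seed: int = 0,
) -> EnvStack:
    """Environmental stack: smooth baseline fields plus smooth scenario deltas.

    Baseline bottom temperatures follow a latitudinal gradient (warmer south)
    with seeded smooth noise.  Scenario year k (0-based index in `years`) adds a
    spatially smooth delta whose spatial mean over sea cells is exactly
    k * warming (temperature) and -k * freshening (salinity).  Static layers
    (depth, mud, median grain size, peak wave stress) are identical across years.
    """
    if not years:
        raise ValueError("years must be non-empty")
    shape = grid.shape
    land = default_land_mask(grid)
    sea = ~land
    lat_frac = ((grid.lat_max - grid.lats) / (grid.lat_max - grid.lat_min))[:, None] * np.ones(shape)

    def rng_for(tag: str) -> np.random.Generator:
        return np.random.default_rng(child_seed(seed, "env", tag))

    base: dict[str, np.ndarray] = {}
    base["temp_jun"] = 10.0 + 7.0 * lat_frac + _smooth_field(shape, rng_for("temp_jun"), 0.6)
    base["temp_feb"] = 3.0 + 5.0 * lat_frac + _smooth_field(shape, rng_for("temp_feb"), 0.5)
    base["sal_jun"] = 33.0 + 2.0 * (1 - lat_frac) + _smooth_field(shape, rng_for("sal_jun"), 0.4)
    depth = 15.0 + 70.0 * (1 - lat_frac) + _smooth_field(shape, rng_for("depth"), 8.0)
    base["depth"] = np.clip(depth, 5.0, None)
    mud = 30.0 + _smooth_field(shape, rng_for("mud"), 18.0)
    base["mud"] = np.clip(mud, 0.0, 100.0)
    base["mgs"] = np.clip(260.0 - 2.0 * base["mud"] + _smooth_field(shape, rng_for("mgs"), 30.0), 50.0, 600.0)
    base["pws"] = np.clip(0.6 + _smooth_field(shape, rng_for("pws"), 0.25), 0.05, 2.5)

    layers: dict[tuple[str, int], np.ndarray] = {}
    for k, year in enumerate(years):
        for name in DYNAMIC_LAYERS:
            values = base[name].copy()
            if k > 0:
                step = warming if name.startswith("temp") else -freshening
                delta = k * step + _smooth_field(shape, rng_for(f"delta_{name}_{year}"), abs(step) * 0.25)
                delta -= delta[sea].mean() - k * step  # exact spatial mean over sea cells
                values = values + delta
            values[land] = np.nan
            layers[(name, year)] = values
        for name in STATIC_LAYERS:
            values = base[name].copy()
            values[land] = np.nan
            layers[(name, year)] = values
    stack = EnvStack(grid=grid, layers=layers, land_mask=land, years=list(years))
    stack.validate()
    return stack


def simulate_species(env: EnvStack, niche: NicheParams) -> dict[int, Surface]:
    """True occurrence probability per year: max_prob x product of Gaussian terms."""
    out: dict[int, Surface] = {}
    for year in env.years:
        prob = np.full(env.grid.shape, niche.max_prob)
        for layer, (mu, sigma) in niche.responses.items():
            x = env.layer(layer, year)
            prob = prob * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))
        prob[env.land_mask] = np.nan
        out[year] = Surface(grid=env.grid, kind="probability", year=year, species=niche.species, values=prob)
    return out


def true_bp_surface(prob: Surface, niche: NicheParams) -> Surface:
    """Expected BP surface from the true probability.

    The survey draws presence ~ Bernoulli(p) and abundance given presence as
    1 + NegBin(mean lambda_max * p), so the unconditional expected abundance is
    A = p * (1 + lambda_max * p); BP is computed from that and the species'
    mean individual biomass, and is exactly 0 wherever p = 0.
    """
    p = prob.values
    A = np.where(np.isfinite(p), p * (1.0 + niche.lambda_max * p), 0.0)
    B = A * niche.mean_ind_biomass
    raw = bp_index.compute_bp(A, B, niche.M, niche.R)
    values = bp_index.log_transform(raw)
    values[~np.isfinite(p)] = np.nan
    return Surface(grid=prob.grid, kind="bp", year=prob.year, species=prob.species, values=values)


def sample_survey(
    truth: dict[str, dict[int, Surface]],
    env: EnvStack,
    n_stations: int,
    niches: list[NicheParams],
    seed: int = 0,
    baseline_year: int | None = None,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Draw a grab survey and assemble the ground-truth bundle.

    Stations are drawn uniformly without replacement from sea cells.  Presence
    is Bernoulli(true probability at the baseline year); abundance given
    presence is 1 + NegBin(mean = lambda_max * p, dispersion k).
    """
    sea_cells = np.argwhere(env.sea_mask)
    if n_stations > len(sea_cells):
        raise ValueError(f"n_stations={n_stations} exceeds {len(sea_cells)} sea cells")
    if baseline_year is None:
        baseline_year = env.years[0]
    rng = np.random.default_rng(child_seed(seed, "survey"))
    chosen = sea_cells[rng.choice(len(sea_cells), size=n_stations, replace=False)]
    lons = env.grid.lons[chosen[:, 1]]
    lats = env.grid.lats[chosen[:, 0]]

    records = []
    for niche in niches:
        prob = truth[niche.species][baseline_year].values[chosen[:, 0], chosen[:, 1]]
        sp_rng = np.random.default_rng(child_seed(seed, "survey", niche.species))
        present = sp_rng.random(n_stations) < prob
        mean = niche.lambda_max * prob
        k = niche.dispersion_k
        extra = sp_rng.negative_binomial(k, k / (k + np.maximum(mean, 1e-9)))
        abundance = np.where(present, 1 + extra, 0)
        for s in range(n_stations):
            records.append(
                {
                    "station": f"st{s:04d}",
                    "lon": round(float(lons[s]), 6),
                    "lat": round(float(lats[s]), 6),
                    "species": niche.species,
                    "abundance": int(abundance[s]),
                    "mean_ind_biomass": niche.mean_ind_biomass,
                }
            )
    stations = pd.DataFrame.from_records(records)
    stations["presence"] = (stations["abundance"] > 0).astype(int)

    bundle = TruthBundle(stations=stations)
    for niche in niches:
        for year, prob in truth[niche.species].items():
            bundle.prob[(niche.species, year)] = prob
            bundle.bp[(niche.species, year)] = true_bp_surface(prob, niche)
    return stations, bundle


def make_world(
    grid: GridSpec = DEFAULT_GRID,
    years: list[int] = DEFAULT_YEARS,
    warming: float = DEFAULT_WARMING,
    freshening: float = DEFAULT_FRESHENING,
    n_stations: int = DEFAULT_N_STATIONS,
    niches: list[NicheParams] | None = None,
    seed: int = 0,
) -> tuple[EnvStack, pd.DataFrame, pd.DataFrame, TruthBundle]:
    """Convenience wrapper: stack + survey + traits + truth for one seed."""
    if niches is None:
        niches = default_niches()
    env = make_env_stack(grid=grid, years=years, warming=warming, freshening=freshening, seed=seed)
    truth = {n.species: simulate_species(env, n) for n in niches}
    stations, bundle = sample_survey(truth, env, n_stations, niches, seed=seed)
    return env, stations, trait_table(niches), bundle
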