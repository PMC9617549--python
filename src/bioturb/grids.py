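"""Grid data model and I/O for environmental stacks, map surfaces and station tables.

All rasters live on a regular WGS84 lon/lat grid of cell centres, row 0 being the
northernmost row.  Land cells carry NaN in memory and an explicit nodata tag on
disk.  Stacks and surfaces are stored as NetCDF (multi-variable for stacks,
single-variable for surfaces) with lon/lat coordinate vectors; station and trait
tables are plain CSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import xarray as xr
import yaml

#: dynamic layers exist once per scenario year
DYNAMIC_LAYERS = ("temp_feb", "temp_jun", "sal_jun")
#: static layers are identical across years
STATIC_LAYERS = ("depth", "mud", "mgs", "pws")
ALL_LAYERS = DYNAMIC_LAYERS + STATIC_LAYERS

STATION_COLUMNS = ["station", "lon", "lat", "species", "abundance", "mean_ind_biomass"]

SURFACE_KINDS = ("probability", "binary", "bp", "difference")


class GridMismatchError(ValueError):
    """Two grids differ by more than half a cell."""


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid (WGS84, decimal degrees), cell-centre registration.

    Row 0 is the northernmost row; columns run west to east.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    cell_size: float

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("extent must have lon_max > lon_min and lat_max > lat_min")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must contain at least one row and one column")

    @property
    def n_rows(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.cell_size))

    @property
    def n_cols(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.cell_size))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lats(self) -> np.ndarray:
        """Cell-centre latitudes, north to south (row order)."""
        return self.lat_max - (np.arange(self.n_rows) + 0.5) * self.cell_size

    @property
    def lons(self) -> np.ndarray:
        """Cell-centre longitudes, west to east (column order)."""
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lonlat_of(self, row: int, col: int) -> tuple[float, float]:
        return (float(self.lons[col]), float(self.lats[row]))

    def index_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Nearest-cell-centre assignment.  Raises for points outside the extent."""
        if not (self.lon_min <= lon <= self.lon_max and self.lat_min <= lat <= self.lat_max):
            raise ValueError(
                f"point ({lon}, {lat}) lies outside the grid extent "
                f"[{self.lon_min}, {self.lon_max}] x [{self.lat_min}, {self.lat_max}]"
            )
        col = int(np.clip(np.floor((lon - self.lon_min) / self.cell_size), 0, self.n_cols - 1))
        row = int(np.clip(np.floor((self.lat_max - lat) / self.cell_size), 0, self.n_rows - 1))
        return (row, col)

    def matches(self, other: "GridSpec", tol_cells: float = 0.5) -> bool:
        """True when the two grids agree within `tol_cells` cells on every edge."""
        tol = tol_cells * self.cell_size
        return (
            abs(self.cell_size - other.cell_size) < 1e-9
            and abs(self.lon_min - other.lon_min) <= tol
            and abs(self.lon_max - other.lon_max) <= tol
            and abs(self.lat_min - other.lat_min) <= tol
            and abs(self.lat_max - other.lat_max) <= tol
        )


#: extent used for the North Sea study area: 60.4 N, 50.9 S, 3.1 W, 10.3 E at 0.06 deg
NORTH_SEA_GRID = GridSpec(lon_min=-3.1, lon_max=10.3, lat_min=50.9, lat_max=60.4, cell_size=0.06)


@dataclass
class EnvStack:
    """Environmental raster stack: per-(layer, year) fields plus a land mask.

    `layers` maps (layer name, scenario year) to a 2-D float array on `grid`;
    static layers are replicated per year so the lookup is uniform.  Land cells
    are NaN in every layer and True in `land_mask`.
    """

    grid: GridSpec
    layers: dict[tuple[str, int], np.ndarray]
    land_mask: np.ndarray  # bool, True = land (excluded)
    years: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.years:
            self.years = sorted({yr for (_, yr) in self.layers})

    @property
    def sea_mask(self) -> np.ndarray:
        return ~self.land_mask

    def layer(self, name: str, year: int) -> np.ndarray:
        key = (name, year)
        if key not in self.layers:
            raise KeyError(f"missing layer {name!r} for year {year}")
        return self.layers[key]

    def validate(self) -> None:
        if self.land_mask.shape != self.grid.shape:
            raise ValueError("land mask shape does not match grid")
        sea = self.sea_mask
        for name in ALL_LAYERS:
            for year in self.years:
                if (name, year) not in self.layers:
                    raise ValueError(f"missing layer {name!r} for year {year}")
                values = self.layers[(name, year)]
                if values.shape != self.grid.shape:
                    raise ValueError(f"layer {name!r}/{year} shape does not match grid")
                bad = sea & ~np.isfinite(values)
                if bad.any():
                    row, col = map(int, np.argwhere(bad)[0])
                    raise ValueError(
                        f"non-finite value on sea cell (row={row}, col={col}) "
                        f"in layer {name!r} for year {year}"
                    )
        baseline = self.years[0]
        for name in STATIC_LAYERS:
            ref = self.layers[(name, baseline)]
            for year in self.years[1:]:
                same = np.allclose(
                    self.layers[(name, year)][sea], ref[sea], rtol=0, atol=0, equal_nan=True
                )
                if not same:
                    raise ValueError(f"static layer {name!r} differs between years")

    def predictor_matrix(self, year: int, cells: np.ndarray | None = None) -> np.ndarray:
        """Stack the seven environmental layers into an (n_cells, 7) matrix.

        `cells` is an (n, 2) array of (row, col) indices; defaults to all sea cells
        in row-major order.
        """
        if cells is None:
            cells = np.argwhere(self.sea_mask)
        out = np.empty((len(cells), len(ALL_LAYERS)))
        rows, cols = cells[:, 0], cells[:, 1]
        for k, name in enumerate(ALL_LAYERS):
            out[:, k] = self.layer(name, year)[rows, cols]
        return out


@dataclass
class Surface:
    """One per-cell field: occurrence probability, binary presence, BP, or a difference."""

    grid: GridSpec
    kind: str
    year: int
    species: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in SURFACE_KINDS:
            raise ValueError(f"unknown surface kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("surface shape does not match grid")

    @property
    def sea_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def validate(self) -> None:
        finite = self.values[np.isfinite(self.values)]
        if self.kind == "probability" and ((finite < 0) | (finite > 1)).any():
            raise ValueError("probability values outside [0, 1]")
        if self.kind == "binary" and (~np.isin(finite, (0.0, 1.0))).any():
            raise ValueError("binary values outside {0, 1}")
        if self.kind == "bp" and (finite < 0).any():
            raise ValueError("bp values must be non-negative (log10(x+1) scale)")

    def total(self, region: np.ndarray | None = None) -> float:
        """Sum of cell values over the region (all finite cells if None)."""
        mask = np.isfinite(self.values)
        if region is not None:
            mask &= region.astype(bool)
        return float(np.nansum(np.where(mask, self.values, 0.0)))


# ---------------------------------------------------------------------------
# NetCDF I/O


def _grid_to_attrs(grid: GridSpec) -> dict:
    return {
        "lon_min": grid.lon_min,
        "lon_max": grid.lon_max,
        "lat_min": grid.lat_min,
        "lat_max": grid.lat_max,
        "cell_size": grid.cell_size,
        "crs": "EPSG:4326",
    }


def _grid_from_attrs(attrs: Mapping) -> GridSpec:
    return GridSpec(
        lon_min=float(attrs["lon_min"]),
        lon_max=float(attrs["lon_max"]),
        lat_min=float(attrs["lat_min"]),
        lat_max=float(attrs["lat_max"]),
        cell_size=float(attrs["cell_size"]),
    )


def write_env_stack(stack: EnvStack, path: str | os.PathLike) -> None:
    stack.validate()
    grid = stack.grid
    data = {}
    for name in DYNAMIC_LAYERS:
        for year in stack.years:
            data[f"{name}_{year}"] = (("lat", "lon"), stack.layer(name, year))
    baseline = stack.years[0]
    for name in STATIC_LAYERS:
        data[name] = (("lat", "lon"), stack.layer(name, baseline))
    data["land_mask"] = (("lat", "lon"), stack.land_mask.astype(np.int8))
    ds = xr.Dataset(
        data,
        coords={"lat": grid.lats, "lon": grid.lons},
        attrs={**_grid_to_attrs(grid), "years": [int(y) for y in stack.years]},
    )
    ds.to_netcdf(path, engine="scipy")


def read_env_stack(path: str | os.PathLike, grid: GridSpec) -> EnvStack:
    """Read an environmental stack from a NetCDF file or a manifest directory.

    A directory must contain ``manifest.yaml`` mapping layer files to (layer, year).
    The stack is validated against `grid`; a mismatch beyond half a cell is an error.
    """
    if os.path.isdir(path):
        return _read_env_stack_manifest(path, grid)
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    file_grid = _grid_from_attrs(ds.attrs)
    if not file_grid.matches(grid):
        raise GridMismatchError(f"stack grid {file_grid} does not match expected {grid}")
    years = [int(y) for y in np.atleast_1d(ds.attrs["years"])]
    land = ds["land_mask"].values.astype(bool)
    layers: dict[tuple[str, int], np.ndarray] = {}
    for year in years:
        for name in DYNAMIC_LAYERS:
            var = f"{name}_{year}"
            if var not in ds:
                raise ValueError(f"missing layer {name!r} for year {year} in {path}")
            layers[(name, year)] = ds[var].values.astype(float)
        for name in STATIC_LAYERS:
            if name not in ds:
                raise ValueError(f"missing static layer {name!r} in {path}")
            layers[(name, year)] = ds[name].values.astype(float)
    stack = EnvStack(grid=grid, layers=layers, land_mask=land, years=years)
    stack.validate()
    return stack


def _read_env_stack_manifest(path: str | os.PathLike, grid: GridSpec) -> EnvStack:
    manifest_path = os.path.join(path, "manifest.yaml")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    years = sorted({int(entry["year"]) for entry in manifest["layers"]})
    layers: dict[tuple[str, int], np.ndarray] = {}
    land: np.ndarray | None = None
    for entry in manifest["layers"]:
        name, year = entry["layer"], int(entry["year"])
        surf = read_surface(os.path.join(path, entry["file"]))
        if not surf.grid.matches(grid):
            raise GridMismatchError(f"layer {name}/{year} grid does not match")
        layers[(name, year)] = surf.values
        if land is None:
            land = ~np.isfinite(surf.values)
    assert land is not None
    for name in STATIC_LAYERS:  # replicate static layers across years
        have = [yr for yr in years if (name, yr) in layers]
        if not have:
            raise ValueError(f"missing static layer {name!r} in manifest")
        for year in years:
            layers.setdefault((name, year), layers[(name, have[0])])
    for name in DYNAMIC_LAYERS:
        for year in years:
            if (name, year) not in layers:
                raise ValueError(f"missing layer {name!r} for year {year} in manifest")
    stack = EnvStack(grid=grid, layers=layers, land_mask=land, years=years)
    stack.validate()
    return stack


def write_surface(surface: Surface, path: str | os.PathLike) -> None:
    """Write one surface as a single-variable georeferenced NetCDF raster."""
    surface.validate()
    grid = surface.grid
    if surface.kind == "binary":
        # integer band with explicit nodata so values on disk are {0, 1, nodata}
        values = np.where(np.isfinite(surface.values), surface.values, -1).astype(np.int8)
        var = xr.DataArray(values, dims=("lat", "lon"), attrs={"nodata": -1})
    else:
        var = xr.DataArray(surface.values, dims=("lat", "lon"), attrs={"nodata": "nan"})
    ds = xr.Dataset(
        {"value": var},
        coords={"lat": grid.lats, "lon": grid.lons},
        attrs={
            **_grid_to_attrs(grid),
            "kind": surface.kind,
            "year": int(surface.year),
            "species": surface.species,
        },
    )
    ds.to_netcdf(path, engine="scipy")


def read_surface(path: str | os.PathLike) -> Surface:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    grid = _grid_from_attrs(ds.attrs)
    values = ds["value"].values.astype(float)
    if ds.attrs["kind"] == "binary":
        values = np.where(values == -1, np.nan, values)
    return Surface(
        grid=grid,
        kind=str(ds.attrs["kind"]),
        year=int(ds.attrs["year"]),
        species=str(ds.attrs["species"]),
        values=values,
    )


# ---------------------------------------------------------------------------
# Station and trait tables


def read_station_table(path: str | os.PathLike, grid: GridSpec | None = None) -> pd.DataFrame:
    """Read a station survey CSV and derive presence flags.

    Columns: station, lon, lat, species, abundance (individuals per 0.1 m^2),
    mean_ind_biomass (g, individual wet mass).  Presence := abundance > 0.
    """
    table = pd.read_csv(path)
    return validate_station_table(table, grid=grid)


def validate_station_table(table: pd.DataFrame, grid: GridSpec | None = None) -> pd.DataFrame:
    missing = [c for c in STATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"station table missing columns: {missing}")
    table = table.copy()
    if (table["abundance"] < 0).any():
        raise ValueError("negative abundance in station table")
    dup = table.duplicated(subset=["station", "species"])
    if dup.any():
        pair = table.loc[dup, ["station", "species"]].iloc[0]
        raise ValueError(f"duplicate (station, species) row: {tuple(pair)}")
    present = table["abundance"] > 0
    bad_biomass = present & ~(table["mean_ind_biomass"] > 0)
    if bad_biomass.any():
        row = table.loc[bad_biomass].iloc[0]
        raise ValueError(
            f"station {row['station']!r} species {row['species']!r}: abundance > 0 "
            "requires positive mean_ind_biomass"
        )
    if grid is not None:
        for _, row in table.drop_duplicates("station").iterrows():
            try:
                grid.index_of(float(row["lon"]), float(row["lat"]))
            except ValueError as exc:
                raise ValueError(f"station {row['station']!r}: {exc}") from exc
    table["presence"] = present.astype(int)
    return table


def write_station_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table[STATION_COLUMNS].to_csv(path, index=False)


def station_cells(table: pd.DataFrame, env: EnvStack) -> pd.DataFrame:
    """Assign each station its nearest grid cell; land-masked stations are rejected."""
    stations = table.drop_duplicates("station")[["station", "lon", "lat"]].copy()
    rows, cols = [], []
    for _, rec in stations.iterrows():
        r, c = env.grid.index_of(float(rec["lon"]), float(rec["lat"]))
        if env.land_mask[r, c]:
            raise ValueError(
                f"station {rec['station']!r} at ({rec['lon']}, {rec['lat']}) falls on a "
                "land-masked cell; remove it or correct its coordinates"
            )
        rows.append(r)
        cols.append(c)
    stations["row"] = rows
    stations["col"] = cols
    return stations.set_index("station")


def read_trait_table(path: str | os.PathLike) -> pd.DataFrame:
    traits = pd.read_csv(path)
    return validate_trait_table(traits)


def validate_trait_table(traits: pd.DataFrame) -> pd.DataFrame:
    for col in ("species", "M", "R"):
        if col not in traits.columns:
            raise ValueError(f"trait table missing column {col!r}")
    if traits["species"].duplicated().any():
        raise ValueError("duplicate species in trait table")
    m, r = traits["M"].to_numpy(), traits["R"].to_numpy()
    if not (np.equal(np.mod(m, 1), 0).all() and np.equal(np.mod(r, 1), 0).all()):
        raise ValueError("mobility and reworking scores must be integers")
    if ((m < 1) | (m > 4)).any():
        raise ValueError("mobility score M must lie in 1..4")
    if ((r < 1) | (r > 5)).any():
        raise ValueError("reworking score R must lie in 1..5")
    return traits


def write_trait_table(traits: pd.DataFrame, path: str | os.PathLike) -> None:
    traits[["species", "M", "R"]].to_csv(path, index=False)
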