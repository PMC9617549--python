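"""Grid model, raster/table I/O round-trips and their validation errors."""

import numpy as np
import pandas as pd
import pytest

from bioturb.grids import (
    GridSpec,
    Surface,
    read_env_stack,
    read_station_table,
    read_surface,
    validate_station_table,
    validate_trait_table,
    station_cells,
    write_env_stack,
    write_station_table,
    write_surface,
)
from bioturb import synth


class TestGridSpec:
    def test_shape_follows_extent_and_resolution(self):
        g = GridSpec(lon_min=-3.1, lon_max=10.3, lat_min=50.9, lat_max=60.4, cell_size=0.06)
        assert g.n_cols == round((10.3 - -3.1) / 0.06)
        assert g.n_rows == round((60.4 - 50.9) / 0.06)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(lon_min=0, lon_max=1, lat_min=0, lat_max=1, cell_size=-0.1),
            dict(lon_min=1, lon_max=0, lat_min=0, lat_max=1, cell_size=0.1),
            dict(lon_min=0, lon_max=1, lat_min=1, lat_max=0, cell_size=0.1),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GridSpec(**kwargs)

    def test_index_lonlat_bijection(self, small_grid):
        """index(lonlat(i, j)) == (i, j) for every cell of the grid."""
        for i in range(small_grid.n_rows):
            for j in range(small_grid.n_cols):
                lon, lat = small_grid.lonlat_of(i, j)
                assert small_grid.index_of(lon, lat) == (i, j)

    def test_row_zero_is_northernmost(self, small_grid):
        assert small_grid.lats[0] > small_grid.lats[-1]

    def test_point_outside_extent_rejected(self, small_grid):
        with pytest.raises(ValueError, match="outside"):
            small_grid.index_of(small_grid.lon_max + 1.0, small_grid.lat_min)


class TestEnvStackIO:
    def test_round_trip_bit_for_bit(self, small_env, tmp_path):
        path = tmp_path / "stack.nc"
        write_env_stack(small_env, path)
        back = read_env_stack(path, small_env.grid)
        assert back.years == small_env.years
        for key, values in small_env.layers.items():
            np.testing.assert_array_equal(back.layers[key], values)
        np.testing.assert_array_equal(back.land_mask, small_env.land_mask)

    def test_missing_layer_year_named_in_error(self, small_env, tmp_path):
        import xarray as xr

        path = tmp_path / "stack.nc"
        write_env_stack(small_env, path)
        ds = xr.open_dataset(path, engine="scipy").load()
        ds = ds.drop_vars("sal_jun_2050")
        broken = tmp_path / "broken.nc"
        ds.to_netcdf(broken, engine="scipy")
        with pytest.raises(ValueError, match="sal_jun.*2050"):
            read_env_stack(broken, small_env.grid)

    def test_nan_on_sea_cell_located(self, small_env, tmp_path):
        import copy

        broken = copy.deepcopy(small_env)
        row, col = map(int, np.argwhere(broken.sea_mask)[0])
        broken.layers[("depth", broken.years[0])][row, col] = np.nan
        with pytest.raises(ValueError, match="sea cell"):
            write_env_stack(broken, tmp_path / "bad.nc")

    def test_grid_mismatch_rejected(self, small_env, tmp_path):
        path = tmp_path / "stack.nc"
        write_env_stack(small_env, path)
        other = GridSpec(lon_min=0.0, lon_max=2.0, lat_min=50.0, lat_max=52.0, cell_size=0.1)
        with pytest.raises(ValueError, match="does not match"):
            read_env_stack(path, other)


class TestSurfaceIO:
    def test_probability_round_trip(self, small_env, tmp_path):
        values = np.where(small_env.sea_mask, 0.25, np.nan)
        surf = Surface(grid=small_env.grid, kind="probability", year=2001, species="sp", values=values)
        path = tmp_path / "prob.nc"
        write_surface(surf, path)
        back = read_surface(path)
        np.testing.assert_allclose(back.values, surf.values)
        assert (back.kind, back.year, back.species) == ("probability", 2001, "sp")

    def test_binary_stored_as_integers(self, small_env, tmp_path):
        import xarray as xr

        values = np.where(small_env.sea_mask, 1.0, np.nan)
        surf = Surface(grid=small_env.grid, kind="binary", year=2050, species="sp", values=values)
        path = tmp_path / "bin.nc"
        write_surface(surf, path)
        raw = xr.open_dataset(path, engine="scipy")["value"].values
        assert set(np.unique(raw)) <= {-1, 0, 1}
        back = read_surface(path)
        np.testing.assert_array_equal(np.isnan(back.values), ~small_env.sea_mask)

    def test_metadata_records_species_and_year(self, small_env, tmp_path):
        values = np.where(small_env.sea_mask, 0.7, np.nan)
        surf = Surface(grid=small_env.grid, kind="bp", year=2099, species="total", values=values)
        path = tmp_path / "bp.nc"
        write_surface(surf, path)
        back = read_surface(path)
        assert back.species == "total" and back.year == 2099

    def test_land_cells_stay_missing_through_io(self, small_env, tmp_path):
        values = np.where(small_env.sea_mask, 0.5, np.nan)
        surf = Surface(grid=small_env.grid, kind="probability", year=2001, species="sp", values=values)
        path = tmp_path / "s.nc"
        write_surface(surf, path)
        back = read_surface(path)
        assert np.isnan(back.values[~small_env.sea_mask]).all()

    def test_invalid_kind_rejected(self, small_env):
        with pytest.raises(ValueError, match="kind"):
            Surface(grid=small_env.grid, kind="weird", year=2001, species="sp", values=np.zeros(small_env.grid.shape))

    def test_probability_range_validated(self, small_env, tmp_path):
        values = np.where(small_env.sea_mask, 1.5, np.nan)
        surf = Surface(grid=small_env.grid, kind="probability", year=2001, species="sp", values=values)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            write_surface(surf, tmp_path / "bad.nc")


class TestStationTable:
    def _table(self):
        return pd.DataFrame(
            {
                "station": ["s1", "s1", "s2", "s2", "s3", "s3"],
                "lon": [2.15, 2.15, 2.45, 2.45, 3.05, 3.05],
                "lat": [52.15, 52.15, 52.45, 52.45, 53.05, 53.05],
                "species": ["a", "b", "a", "b", "a", "b"],
                "abundance": [4, 1, 2, 0, 0, 3],
                "mean_ind_biomass": [0.5, 1.0, 0.5, 1.0, 0.5, 1.0],
            }
        )

    def test_presence_derived_from_abundance(self):
        table = validate_station_table(self._table())
        assert table["presence"].tolist() == [1, 1, 1, 0, 0, 1]

    def test_round_trip(self, tmp_path):
        path = tmp_path / "stations.csv"
        write_station_table(self._table(), path)
        back = read_station_table(path)
        pd.testing.assert_frame_equal(
            back.drop(columns="presence"), self._table(), check_dtype=False
        )

    def test_negative_abundance_rejected(self):
        bad = self._table()
        bad.loc[0, "abundance"] = -1
        with pytest.raises(ValueError, match="negative"):
            validate_station_table(bad)

    def test_missing_biomass_with_abundance_rejected(self):
        bad = self._table()
        bad.loc[0, "mean_ind_biomass"] = np.nan
        with pytest.raises(ValueError, match="biomass"):
            validate_station_table(bad)

    def test_duplicate_station_species_rejected(self):
        bad = pd.concat([self._table(), self._table().iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            validate_station_table(bad)

    def test_station_outside_grid_rejected(self, small_grid):
        bad = self._table()
        bad.loc[0, "lon"] = 99.0
        with pytest.raises(ValueError, match="outside"):
            validate_station_table(bad, grid=small_grid)

    def test_station_on_land_rejected(self, small_env):
        land = np.argwhere(small_env.land_mask)
        if len(land) == 0:
            pytest.skip("no land cells in this small world")
        lon, lat = small_env.grid.lonlat_of(*map(int, land[0]))
        table = self._table()
        table.loc[0:1, "lon"] = lon
        table.loc[0:1, "lat"] = lat
        with pytest.raises(ValueError, match="land"):
            station_cells(validate_station_table(table), small_env)

    def test_synthetic_survey_round_trips(self, small_world, tmp_path):
        _, stations, _, _ = small_world
        path = tmp_path / "synth_stations.csv"
        write_station_table(stations, path)
        back = read_station_table(path)
        pd.testing.assert_frame_equal(
            back, stations.reset_index(drop=True), check_dtype=False
        )


class TestTraitTable:
    def test_scores_validated(self):
        with pytest.raises(ValueError, match="M"):
            validate_trait_table(pd.DataFrame({"species": ["a"], "M": [5], "R": [3]}))
        with pytest.raises(ValueError, match="R"):
            validate_trait_table(pd.DataFrame({"species": ["a"], "M": [2], "R": [6]}))
        ok = validate_trait_table(pd.DataFrame({"species": ["a"], "M": [4], "R": [5]}))
        assert len(ok) == 1
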