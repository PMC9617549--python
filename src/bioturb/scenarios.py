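"""Scenario aggregation: BP_t, gain/loss vs the baseline year, species
contributions and difference maps."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import GridSpec, Surface


def gain_loss(
    surfaces: dict[tuple[str, int], Surface],
    baseline_year: int,
    region: Surface | None = None,
) -> pd.DataFrame:
    """Total BP per species/year and percent change relative to the baseline year.

    Totals are plain sums of cell values over the region (all sea cells when no
    region mask is given); the baseline year is set to 100%, so its change is 0.
    Species with a zero baseline total get a null (not infinite) percent change.
    """
    species = sorted({sp for (sp, _) in surfaces})
    years = sorted({yr for (_, yr) in surfaces})
    region_mask = None
    if region is not None:
        region_mask = region.values == 1
    rows = []
    for sp in species:
        if (sp, baseline_year) not in surfaces:
            raise ValueError(f"missing baseline year {baseline_year} surface for {sp!r}")
        base_total = surfaces[(sp, baseline_year)].total(region_mask)
        for yr in years:
            if (sp, yr) not in surfaces:
                continue
            total = surfaces[(sp, yr)].total(region_mask)
            if base_total == 0:
                pct = np.nan
            else:
                pct = 100.0 * (total - base_total) / base_total
            rows.append({"species": sp, "year": yr, "total_bp": total, "pct_change": pct})
    return pd.DataFrame(rows)


def relative_contribution(
    surfaces: dict[tuple[str, int], Surface],
    year: int,
    region: Surface | None = None,
) -> pd.DataFrame:
    """Per-species share (%) of the regional BP_t for one year; shares sum to 100."""
    region_mask = region.values == 1 if region is not None else None
    totals = {
        sp: surf.total(region_mask) for (sp, yr), surf in surfaces.items() if yr == year and sp != "total"
    }
    if not totals:
        raise ValueError(f"no species surfaces for year {year}")
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError(f"total BP is zero for year {year}; contributions undefined")
    return pd.DataFrame(
        {
            "species": list(totals),
            "year": year,
            "contribution_pct": [100.0 * t / grand for t in totals.values()],
        }
    )


def bp_weighted_latitude(surface: Surface) -> float:
    """BP-weighted mean latitude of a surface — the distribution's centroid.

    A poleward (northward) range shift under warming raises this value.
    Undefined (NaN) when the surface sums to zero.
    """
    values = surface.values
    lats = surface.grid.lats[:, None] * np.ones(surface.grid.shape)
    mask = np.isfinite(values)
    total = values[mask].sum()
    if total == 0:
        return float("nan")
    return float((values[mask] * lats[mask]).sum() / total)


def difference_map(surface_a: Surface, surface_b: Surface) -> Surface:
    """Cell-wise (b - a), e.g. a later scenario year minus the baseline."""
    if not surface_a.grid.matches(surface_b.grid):
        raise ValueError("grid mismatch between surfaces")
    if surface_a.species != surface_b.species:
        raise ValueError("species mismatch between surfaces")
    values = surface_b.values - surface_a.values
    return Surface(
        grid=surface_a.grid,
        kind="difference",
        year=surface_b.year,
        species=surface_a.species,
        values=values,
    )


def region_mask_southern(grid: GridSpec, lat_cut: float, land_mask: np.ndarray | None = None) -> Surface:
    """Binary region mask: 1 for sea cells whose centre latitude is below lat_cut."""
    if not grid.lat_min <= lat_cut <= grid.lat_max:
        raise ValueError(f"lat_cut {lat_cut} outside grid extent [{grid.lat_min}, {grid.lat_max}]")
    in_region = (grid.lats[:, None] < lat_cut) * np.ones(grid.shape)
    values = in_region.astype(float)
    if land_mask is not None:
        values[land_mask] = np.nan
    return Surface(grid=grid, kind="binary", year=0, species="region", values=values)
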