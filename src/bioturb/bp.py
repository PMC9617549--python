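"""Species bioturbation potential (BP).

The population bioturbation potential of species i at a station is

    BP_p = (B_i / A_i)^0.5 * A_i * M_i * R_i

with A_i the abundance (individuals per 0.1 m^2), B_i the total wet biomass at
the station (g per 0.1 m^2, i.e. mean individual mass x abundance), M_i the
mobility score (1 = fixed tubes .. 4 = free movement via burrows) and R_i the
sediment-reworking score (1 = epifauna .. 5 = regenerators).  (B/A)^0.5 is thus
the square root of mean individual mass.  BP_p is log10(x+1) transformed to
down-scale large values, and the total BP_t is the sum of the (transformed)
per-species surfaces.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import Surface


def compute_bp(A, B, M, R):
    """Raw bioturbation potential (B/A)^0.5 * A * M * R; zero where A = 0.

    Accepts scalars or aligned arrays.  B > 0 with A = 0 is contradictory and
    raises; M and R must be valid categorical scores.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    M = np.asarray(M)
    R = np.asarray(R)
    if (A < 0).any() or (B < 0).any():
        raise ValueError("abundance and biomass must be non-negative")
    if ((M < 1) | (M > 4)).any():
        raise ValueError("mobility score M must lie in 1..4")
    if ((R < 1) | (R > 5)).any():
        raise ValueError("reworking score R must lie in 1..5")
    if ((B > 0) & (A == 0)).any():
        raise ValueError("positive biomass with zero abundance")
    with np.errstate(divide="ignore", invalid="ignore"):
        bp = np.where(A > 0, np.sqrt(np.where(A > 0, B, 0) / np.where(A > 0, A, 1)) * A * M * R, 0.0)
    if bp.ndim == 0:
        return float(bp)
    return bp


def log_transform(bp_raw):
    """log10(x+1) transform of raw BP; maps 0 to 0 and compresses large values."""
    bp_raw = np.asarray(bp_raw, dtype=float)
    if (bp_raw < 0).any():
        raise ValueError("raw BP must be non-negative")
    out = np.log10(bp_raw + 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def station_bp_table(stations: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Per-(station, species) BP table from a survey and a trait table.

    Total biomass B = abundance x mean individual biomass.  Every surveyed
    species must appear in the trait table.
    """
    missing = set(stations["species"]) - set(traits["species"])
    if missing:
        raise ValueError(f"species missing from trait table: {sorted(missing)}")
    merged = stations.merge(traits[["species", "M", "R"]], on="species", how="left")
    A = merged["abundance"].to_numpy(dtype=float)
    B = A * merged["mean_ind_biomass"].to_numpy(dtype=float)
    bp_raw = compute_bp(A, B, merged["M"].to_numpy(), merged["R"].to_numpy())
    return pd.DataFrame(
        {
            "station": merged["station"],
            "species": merged["species"],
            "A": A,
            "B": B,
            "bp_raw": np.atleast_1d(bp_raw),
            "bp_log": np.atleast_1d(log_transform(bp_raw)),
        }
    )


def sum_bp_total(surfaces: list[Surface], year: int) -> Surface:
    """Cell-wise sum of per-species BP surfaces for one year (species = "total")."""
    if not surfaces:
        raise ValueError("no surfaces to sum")
    grid = surfaces[0].grid
    total = np.zeros(grid.shape)
    sea = np.isfinite(surfaces[0].values)
    for surf in surfaces:
        if surf.kind != "bp":
            raise ValueError(f"expected bp surfaces, got {surf.kind!r}")
        if surf.year != year:
            raise ValueError(f"year mismatch: {surf.year} != {year}")
        if not surf.grid.matches(grid):
            raise ValueError("grid mismatch between BP surfaces")
        total += np.where(np.isfinite(surf.values), surf.values, 0.0)
    total[~sea] = np.nan
    return Surface(grid=grid, kind="bp", year=year, species="total", values=total)
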