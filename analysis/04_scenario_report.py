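#!/usr/bin/env python
"""Scenario aggregation: BP_t, gain/loss relative to the baseline year,
relative species contributions in the southern region, and difference maps.

Reads the masked BP surfaces from 03, sums them into BP_t per year, reports
percent gain/loss per species and for the total (baseline year = 100%) over
the whole grid and the southern sub-region, the per-year contribution shares,
and writes BP_t difference maps (later year minus baseline).
"""

import argparse
import os

import pandas as pd

from bioturb import bp as bpi
from bioturb import scenarios, synth
from bioturb.grids import read_surface, write_surface


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--bp-dir", default="results/bp")
    parser.add_argument("--baseline-year", type=int, default=2001)
    parser.add_argument("--lat-cut", type=float, default=53.0)
    parser.add_argument("--out-dir", default="results/report")
    args = parser.parse_args()

    surfaces = {}
    for name in sorted(os.listdir(args.bp_dir)):
        if name.startswith("bp_") and "unmasked" not in name and name.endswith(".nc"):
            surf = read_surface(os.path.join(args.bp_dir, name))
            surfaces[(surf.species, surf.year)] = surf
    years = sorted({yr for (_, yr) in surfaces})
    species = sorted({sp for (sp, _) in surfaces})
    print(f"loaded {len(surfaces)} BP surfaces: {species} x {years}")

    grid = next(iter(surfaces.values())).grid
    bp_total = {
        yr: bpi.sum_bp_total([surfaces[(sp, yr)] for sp in species], yr) for yr in years
    }
    with_total = dict(surfaces)
    for yr, surf in bp_total.items():
        with_total[("total", yr)] = surf

    southern = scenarios.region_mask_southern(grid, args.lat_cut)
    gl = scenarios.gain_loss(with_total, args.baseline_year)
    gl_south = scenarios.gain_loss(with_total, args.baseline_year, region=southern)
    contrib = pd.concat(
        [scenarios.relative_contribution(surfaces, yr, region=southern) for yr in years],
        ignore_index=True,
    )

    os.makedirs(args.out_dir, exist_ok=True)
    gl.to_csv(os.path.join(args.out_dir, "gain_loss.csv"), index=False, float_format="%.6f", na_rep="null")
    gl_south.to_csv(os.path.join(args.out_dir, "gain_loss_southern.csv"), index=False,
                    float_format="%.6f", na_rep="null")
    contrib.to_csv(os.path.join(args.out_dir, "contributions.csv"), index=False, float_format="%.6f")
    for yr in years:
        if yr == args.baseline_year:
            continue
        diff = scenarios.difference_map(bp_total[args.baseline_year], bp_total[yr])
        write_surface(diff, os.path.join(args.out_dir, f"diff_total_{args.baseline_year}_{yr}.nc"))

    print("\ngain/loss vs baseline (whole grid, %):")
    print(gl.pivot(index="species", columns="year", values="pct_change").round(1).to_string())
    print(f"\ngain/loss vs baseline (south of {args.lat_cut} N, %):")
    print(gl_south.pivot(index="species", columns="year", values="pct_change").round(1).to_string())
    print("\ncontribution to southern BP_t (%):")
    print(contrib.pivot(index="species", columns="year", values="contribution_pct").round(1).to_string())


if __name__ == "__main__":
    main()
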