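#!/usr/bin/env python
"""Step 2: random-forest regression of station BP on environment + occurrence.

Reads the synthetic world (01) and the consensus/binary surfaces (02), builds
the per-species regression tables (seven environmental predictors plus the
step-1 probability of occurrence; response = log-scaled station BP_p),
cross-validates (10-fold, or 6-fold below 50 presences), fits on all stations,
predicts per-cell BP for every scenario year, and applies the hurdle mask.
Writes masked/unmasked BP surfaces and the evaluation table under results/bp/.
"""

import argparse
import os

import pandas as pd

import bioturb
from bioturb import bp as bpi
from bioturb import regression as reg
from bioturb import synth
from bioturb.grids import (
    read_env_stack,
    read_station_table,
    read_surface,
    read_trait_table,
    station_cells,
    write_surface,
)
from bioturb.seeding import child_seed


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--world-dir", default="results/world")
    parser.add_argument("--sdm-dir", default="results/sdm")
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", default="results/bp")
    args = parser.parse_args()

    env = read_env_stack(os.path.join(args.world_dir, "env_stack.nc"), synth.DEFAULT_GRID)
    stations = read_station_table(os.path.join(args.world_dir, "stations.csv"), grid=env.grid)
    traits = read_trait_table(os.path.join(args.world_dir, "traits.csv"))
    cells = station_cells(stations, env)
    bp_station = bpi.station_bp_table(stations, traits)
    baseline = env.years[0]

    os.makedirs(args.out_dir, exist_ok=True)
    rows = []
    for species in sorted(stations["species"].unique()):
        n_presences = int(stations.loc[stations["species"] == species, "presence"].sum())
        n_folds = reg.choose_n_folds(n_presences)
        occ = read_surface(os.path.join(args.sdm_dir, f"prob_{species}_{baseline}.nc"))
        table = reg.build_regression_table(bp_station, cells, env, occ, species, baseline)
        seed = child_seed(args.seed, "bp", species)
        ev = reg.cross_validate(table, n_folds, seed=seed, species=species)
        model = reg.fit_bp_model(table, seed=seed)
        ev.importance = reg.variable_importance(model, table, seed=seed)
        rows.append({
            "species": species, "n_presences": n_presences, "n_folds": n_folds,
            "mae": round(ev.mae, 4), "rmse": round(ev.rmse, 4),
            "mae_pct": round(ev.mae_pct, 2), "rmse_pct": round(ev.rmse_pct, 2),
            **{f"imp_{k}": round(v, 2) for k, v in ev.importance.items()},
        })
        for year in env.years:
            occ_y = read_surface(os.path.join(args.sdm_dir, f"prob_{species}_{year}.nc"))
            binary_y = read_surface(os.path.join(args.sdm_dir, f"binary_{species}_{year}.nc"))
            surf = reg.predict_bp_surface(model, env, occ_y, year)
            write_surface(surf, os.path.join(args.out_dir, f"bp_unmasked_{species}_{year}.nc"))
            masked = reg.zero_inflate_mask(surf, binary_y)
            write_surface(masked, os.path.join(args.out_dir, f"bp_{species}_{year}.nc"))

    eval_table = pd.DataFrame(rows)
    eval_table.to_csv(os.path.join(args.out_dir, "regression_evaluation.csv"), index=False)
    print("BP regression evaluation (errors on the log10(BP+1) scale):")
    print(eval_table[["species", "n_presences", "n_folds", "mae", "rmse", "mae_pct", "rmse_pct"]]
          .to_string(index=False))


if __name__ == "__main__":
    main()
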