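#!/usr/bin/env python
"""Build the default synthetic study system and write it under results/world/.

Produces the environmental stack (three scenario years with smooth warming and
freshening deltas), the 284-station grab survey, the species trait table, and
the ground-truth probability and expected-BP rasters for the three virtual
species.  Everything downstream (02-04) reads from this directory.
"""

import argparse
import os

from bioturb import synth
from bioturb.grids import write_env_stack, write_station_table, write_surface, write_trait_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", default="results/world")
    args = parser.parse_args()

    env, stations, traits, truth = synth.make_world(seed=args.seed)
    os.makedirs(args.out_dir, exist_ok=True)
    write_env_stack(env, os.path.join(args.out_dir, "env_stack.nc"))
    write_station_table(stations, os.path.join(args.out_dir, "stations.csv"))
    write_trait_table(traits, os.path.join(args.out_dir, "traits.csv"))
    truth_dir = os.path.join(args.out_dir, "truth")
    os.makedirs(truth_dir, exist_ok=True)
    for (sp, year), surf in truth.prob.items():
        write_surface(surf, os.path.join(truth_dir, f"true_prob_{sp}_{year}.nc"))
    for (sp, year), surf in truth.bp.items():
        write_surface(surf, os.path.join(truth_dir, f"true_bp_{sp}_{year}.nc"))

    presences = stations.groupby("species")["presence"].sum()
    print(f"world written to {args.out_dir}")
    print(f"grid: {env.grid.n_rows} x {env.grid.n_cols} cells, {int(env.sea_mask.sum())} sea")
    print(f"stations: {stations['station'].nunique()}; presences per species:")
    print(presences.to_string())


if __name__ == "__main__":
    main()
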