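#!/usr/bin/env python
"""Simulate the study landscape: six covariate layers and observation counts.

Stands in for a national citizen-science extraction: a 500x500 km region of
10 km cells where recorder effort rises with road access and population and
falls with elevation and steepness.  Writes ESRI ASCII rasters plus a tidy
CSV under results/landscape/ and prints the realised layer ranges so they
can be eyeballed against what real landscapes look like.

Run:  python analysis/01_simulate_landscape.py [--seed 11]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from ignoscore.io import layer_to_tidy, write_ascii_grid
from ignoscore.synthetic import SyntheticScenario, simulate_scenario

OUT = Path("results/landscape")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=11)
    args = parser.parse_args()

    scenario = SyntheticScenario(seed=args.seed)
    layers, counts = simulate_scenario(scenario)

    OUT.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(OUT / "counts.asc", counts.counts.astype(float), counts.grid)
    for layer in layers.values():
        write_ascii_grid(OUT / f"covariate_{layer.name}.asc", layer.values, layer.grid)
    pd.concat([layer_to_tidy(l) for l in layers.values()], ignore_index=True).to_csv(
        OUT / "covariates.csv", index=False)

    print(f"scenario seed {args.seed}: {counts.grid.n_rows}x{counts.grid.n_cols} cells "
          f"of {counts.grid.cell_size/1000:.0f} km")
    print(f"observation records: {counts.total:,} "
          f"(mean {counts.counts.mean():.1f}/cell, max {counts.counts.max():,}, "
          f"{(counts.counts == 0).mean():.1%} of cells never visited)")
    print(f"{'layer':<26}{'min':>10}{'median':>10}{'max':>12}  units")
    for name, layer in layers.items():
        v = layer.values
        print(f"{name:<26}{np.nanmin(v):>10.3g}{np.nanmedian(v):>10.3g}"
              f"{np.nanmax(v):>12.5g}  {layer.units}")
    print(f"outputs in {OUT}/")


if __name__ == "__main__":
    main()
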