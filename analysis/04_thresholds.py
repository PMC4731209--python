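#!/usr/bin/env python
"""Fitted ignorance curves and 0.5-threshold covariate values at O_0.5 = 1.

Refits the selected model for each covariate (longer chains than the
screening pass), plots ignorance against each covariate, and solves for the
covariate values where the fitted curve crosses 0.5 — the point at which, for
O_0.5 = 1, at least one recorder is effectively present.  Crossings carry
95% posterior intervals obtained by solving the root per posterior draw.

Run:  python analysis/04_thresholds.py [--seed 11]
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from ignoscore.beta_glm import MCMCSettings, boundary_adjust, fit_covariate_models, fitted_curve
from ignoscore.io import read_ascii_grid
from ignoscore.thresholds import threshold_report

LANDSCAPE = Path("results/landscape")
IGNORANCE = Path("results/ignorance")
MODELS = Path("results/models")
OUT = Path("results/thresholds")

UNITS = {"elevation": "m", "slope": "%", "road_density": "km/km²",
         "path_density": "km/km²", "population_density": "people/km²",
         "log_population_density": "log(people/km²)"}


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=11)
    parser.add_argument("--no-figure", action="store_true")
    args = parser.parse_args()

    selection_table = pd.read_csv(MODELS / "selection_table.csv")
    at_o1 = selection_table[selection_table["o_half"] == 1.0]
    scores, _, _ = read_ascii_grid(IGNORANCE / "ignorance_o1.asc")
    y = boundary_adjust(scores.ravel())

    chosen_fits = []
    curves = []
    for _, row in at_o1.iterrows():
        name = row["covariate"]
        x = read_ascii_grid(LANDSCAPE / f"covariate_{name}.asc")[0].ravel()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits, selection = fit_covariate_models(
                y, x, MCMCSettings(iterations=2000, burn_in=1500, chains=3, seed=args.seed),
                covariate_name=name, taxon="synthetic-taxon", o_half=1.0)
        best = selection.chosen
        print(f"{name:<26} degree {best.model.degree}  "
              f"(screening pass chose {int(row['chosen_degree'])})")
        if best.model.degree == 0:
            continue
        chosen_fits.append(best)
        xs = np.linspace(x.min(), x.max(), 250)
        _, mu = fitted_curve(best, xs)
        curves.append(pd.DataFrame({"covariate": name, "x": xs, "mu": mu}))

    OUT.mkdir(parents=True, exist_ok=True)
    table = threshold_report(chosen_fits, target=0.5)
    table.to_csv(OUT / "thresholds.csv", index=False, float_format="%.6g")
    pd.concat(curves, ignore_index=True).to_csv(OUT / "fitted_curves.csv",
                                                index=False, float_format="%.6g")

    print("\ncovariate values where fitted ignorance crosses 0.5 "
          "(in-range crossings only):")
    shown = table[table["in_range"]]
    for _, r in shown.iterrows():
        print(f"  {r['covariate']:<26} {r['crossing']:10.3g} {UNITS[r['covariate']]:<16}"
              f" [{r['lo95']:.3g}, {r['hi95']:.3g}]  ({r['direction']})")
    never = sorted(set(f.model.covariate_name for f in chosen_fits)
                   - set(shown["covariate"]))
    if never:
        print("  curves never spanning 0.5 within the observed range: " + ", ".join(never))

    if not args.no_figure:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 3, figsize=(12, 7), sharey=True)
        for ax, df in zip(axes.ravel(), curves):
            name = df["covariate"].iloc[0]
            ax.plot(df["x"], df["mu"], lw=2)
            ax.axhline(0.5, color="grey", ls=":")
            for _, r in table[(table["covariate"] == name) & table["in_range"]].iterrows():
                ax.axvline(r["crossing"], color="firebrick", ls="--", alpha=0.7)
            ax.set_xlabel(f"{name} ({UNITS[name]})")
            ax.set_ylim(0, 1)
        axes[0, 0].set_ylabel("fitted ignorance")
        axes[1, 0].set_ylabel("fitted ignorance")
        fig.suptitle("Fitted ignorance curves at O_0.5 = 1 (dashed: 0.5 thresholds)")
        fig.tight_layout()
        fig.savefig(OUT / "fitted_curves.png", dpi=110)
        print(f"figure: {OUT / 'fitted_curves.png'}")
    print(f"outputs in {OUT}/")


if __name__ == "__main__":
    main()
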