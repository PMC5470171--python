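"""Pavement-cell shape analysis: per-cell convexity, the binned
area-convexity relationship per genotype, and stomatal indices for
example epidermal counts.

Reads results/data/cells.csv (+ cell_genotypes.csv), writes
results/convexity.csv and results/convexity_curve.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from leafpheno import io
from leafpheno.morphometrics import EpidermisCounts, convexity_vs_area, stomatal_index


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    out = io.ensure_dir(args.out)

    polys = io.read_polygons_csv(args.data / "cells.csv")
    genotype_of = dict(
        pd.read_csv(args.data / "cell_genotypes.csv").itertuples(index=False)
    )
    cells = [(p, genotype_of[p.cell_id]) for p in polys]
    per_cell, curve = convexity_vs_area(cells)
    per_cell.to_csv(out / "convexity.csv", index=False)
    curve.to_csv(out / "convexity_curve.csv", index=False)

    for name, sub in per_cell.groupby("genotype"):
        print(
            f"{name}: median convexity {sub['convexity'].median():.3f}, "
            f"median cell area {sub['area_um2'].median():,.0f} um^2 (n={len(sub)})"
        )

    # stomatal index for illustrative guard/epidermal counts
    for label, counts in {
        "WT-like": EpidermisCounts(62, 240),
        "OE-like": EpidermisCounts(41, 230),
    }.items():
        print(f"{label}: stomatal index {stomatal_index(counts):.1f}%")


if __name__ == "__main__":
    main()
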