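"""Simulate the full synthetic study: three genotypes of a leaf-growth
time course (wild-type-like arresting at 15 DAS, overexpression-like at
10 DAS, an intermediate at 12 DAS), pavement-cell outlines, ploidy
counts, and an RNA-seq count matrix with planted fold changes.

Writes every pipeline input under results/data/.
"""

import argparse
from pathlib import Path

from leafpheno import io
from leafpheno.morphometrics import CellPolygon
from leafpheno.synthetic import (
    growth_preset,
    simulate_counts,
    simulate_growth,
    simulate_ploidy,
    simulate_polygons,
)

GENOTYPES = ("WT-like", "OE-mild", "OE-like")
PLOIDY_FRACTIONS = {
    "WT-like": (0.55, 0.30, 0.12, 0.03),
    "OE-mild": (0.45, 0.30, 0.17, 0.08),
    "OE-like": (0.40, 0.30, 0.20, 0.10),
}
LOBE_AMPLITUDE = {"WT-like": 0.35, "OE-mild": 0.30, "OE-like": 0.25}


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/data"))
    args = parser.parse_args()
    out = io.ensure_dir(args.out)

    series = []
    for k, name in enumerate(GENOTYPES):
        params = growth_preset(name, seed=args.seed * 100 + k)
        s, truth = simulate_growth(params)
        series.append(s)
        print(
            f"{name}: arrest day {params.t_arrest:.0f}, "
            f"true final cell number {truth.table['cell_number'].iloc[-1]:,.0f}"
        )
    io.write_growth_csv(series, out / "growth.csv")

    polygons = []
    rows = []
    for k, name in enumerate(GENOTYPES):
        polys = [
            CellPolygon(f"{name}-{p.cell_id}", p.vertices)
            for p in simulate_polygons(
                120, LOBE_AMPLITUDE[name], 8, seed=args.seed * 100 + 10 + k
            )
        ]
        polygons.extend(polys)
        rows.extend((p.cell_id, name) for p in polys)
        d = simulate_ploidy(
            PLOIDY_FRACTIONS[name], n_nuclei=10_000, seed=args.seed * 100 + 20 + k
        )
        io.write_ploidy_csv(
            [{"sample": f"{name}-16das", "genotype": name, "das": 16,
              "distribution": d}],
            out / f"ploidy_{name}.csv",
        )
    io.write_polygons_csv(polygons, out / "cells.csv")
    (out / "cell_genotypes.csv").write_text(
        "cell_id,genotype\n" + "\n".join(f"{c},{g}" for c, g in rows) + "\n"
    )

    matrix, truth_labels = simulate_counts(
        n_genes=2000, n_per_group=3, frac_de=0.05, log2fc_de=2.0,
        seed=args.seed * 100 + 30,
    )
    io.write_counts_tsv(matrix, out / "counts.tsv")
    io.write_groups_csv(matrix.groups, out / "groups.csv")
    (out / "de_truth.csv").write_text(
        "gene_id,planted\n"
        + "\n".join(
            f"{g},{int(t)}" for g, t in zip(matrix.genes, truth_labels)
        )
        + "\n"
    )
    print(f"planted DE genes: {int(truth_labels.sum())} of {len(truth_labels)}")
    print(f"inputs written under {out}")


if __name__ == "__main__":
    main()
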