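"""Differential-expression analysis of the simulated count matrix:
beta-binomial proportion test, BH-FDR and fold-change filtering, then
QT clustering of the significant genes' depth-scaled log profiles;
recovery is scored against the planted truth labels.

Reads results/data/counts.tsv (+ groups.csv, de_truth.csv), writes
results/de_results.csv and results/clusters.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from leafpheno import io
from leafpheno.transcriptomics import differential_expression, qt_cluster, scale_to_depth


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--min-size", type=int, default=15)
    args = parser.parse_args()
    out = io.ensure_dir(args.out)

    matrix = io.read_counts_tsv(
        args.data / "counts.tsv", groups=io.read_groups_csv(args.data / "groups.csv")
    )
    result = differential_expression(matrix, "A", "B")
    io.write_de_csv(result, out / "de_results.csv")

    truth = pd.read_csv(args.data / "de_truth.csv", index_col="gene_id")["planted"]
    called = result.table["significant"]
    tp = int((called & truth.astype(bool)).sum())
    print(
        f"{result.n_significant} genes significant "
        f"(FDR<{result.alpha}, |log2FC|>{result.fc_threshold}); "
        f"recovered {tp}/{int(truth.sum())} planted, "
        f"{result.n_significant - tp} false calls"
    )

    sig = result.significant_genes
    if len(sig) >= args.min_size:
        profiles = np.log2(scale_to_depth(matrix).loc[sig] + 1.0)
        cs = qt_cluster(profiles, min_size=args.min_size)
        io.write_clusters_csv(cs, out / "clusters.csv")
        print(
            f"QT clusters: sizes {[len(c) for c in cs.clusters]}, "
            f"diameters {[round(d, 3) for d in cs.diameters]}, "
            f"{len(cs.unclustered)} unclustered"
        )


if __name__ == "__main__":
    main()
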