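"""Endoreduplication index per genotype from simulated flow-cytometry
ploidy counts, with multinomial-bootstrap confidence intervals.

Reads results/data/ploidy_*.csv, writes results/ei.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from leafpheno import io
from leafpheno.ploidy import ei_with_ci


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()
    out = io.ensure_dir(args.out)

    records = []
    for path in sorted(args.data.glob("ploidy_*.csv")):
        for row in io.read_ploidy_csv(path):
            ei, (lo, hi) = ei_with_ci(row["distribution"], seed=args.seed)
            records.append(
                {"sample": row["sample"], "genotype": row["genotype"],
                 "das": row["das"], "ei": ei, "ci_lo": lo, "ci_hi": hi,
                 "n_nuclei": row["distribution"].total}
            )
            print(
                f"{row['genotype']}: EI {ei:.3f} "
                f"(95% CI {lo:.3f}-{hi:.3f}, {row['distribution'].total} nuclei)"
            )
    pd.DataFrame(records).to_csv(out / "ei.csv", index=False)


if __name__ == "__main__":
    main()
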