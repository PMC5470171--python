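"""CSV/TSV readers and writers for the pipeline's domain objects.

All formats are plain text and round-trip losslessly:

* growth series CSV: genotype, das, replicate, blade_area_mm2,
  mean_cell_area_um2
* polygon CSV: cell_id, vertex_index, x_um, y_um
* ploidy CSV: sample, genotype, das, n2c, n4c, n8c, n16c
* counts TSV: gene_id, length_bp, then one column per sample
* groups CSV: sample, group
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from leafpheno.kinematics import GrowthSeries, KinematicProfile
from leafpheno.morphometrics import CellPolygon
from leafpheno.ploidy import PloidyDistribution
from leafpheno.transcriptomics import ClusterSet, CountMatrix, DEResult

__all__ = [
    "write_growth_csv",
    "read_growth_csv",
    "write_polygons_csv",
    "read_polygons_csv",
    "write_ploidy_csv",
    "read_ploidy_csv",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_groups_csv",
    "read_groups_csv",
    "write_profile_csv",
    "write_de_csv",
    "write_clusters_csv",
]


def write_growth_csv(series_list: list[GrowthSeries], path) -> None:
    frames = [s.data.assign(genotype=s.genotype) for s in series_list]
    out = pd.concat(frames, ignore_index=True)[
        ["genotype", "das", "replicate", "blade_area_mm2", "mean_cell_area_um2"]
    ]
    out.to_csv(path, index=False)


def read_growth_csv(path) -> list[GrowthSeries]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        GrowthSeries(genotype=str(g), data=sub.drop(columns="genotype"))
        for g, sub in df.groupby("genotype", sort=False)
    ]


def write_polygons_csv(polygons: list[CellPolygon], path) -> None:
    rows = []
    for poly in polygons:
        for k, (x, y) in enumerate(poly.vertices):
            rows.append((poly.cell_id, k, x, y))
    pd.DataFrame(
        rows, columns=["cell_id", "vertex_index", "x_um", "y_um"]
    ).to_csv(path, index=False, float_format="%.17g")  # lossless float64


def read_polygons_csv(path) -> list[CellPolygon]:
    df = pd.read_csv(path, float_precision="round_trip")
    polys = []
    for cid, sub in df.groupby("cell_id", sort=False):
        sub = sub.sort_values("vertex_index")
        polys.append(
            CellPolygon(
                cell_id=str(cid),
                vertices=sub[["x_um", "y_um"]].to_numpy(dtype=float),
            )
        )
    return polys


def write_ploidy_csv(rows: list[dict], path) -> None:
    """Each row: sample, genotype, das plus a PloidyDistribution under
    key 'distribution'."""
    out = []
    for row in rows:
        d: PloidyDistribution = row["distribution"]
        out.append(
            {
                "sample": row["sample"],
                "genotype": row.get("genotype", ""),
                "das": row.get("das", ""),
                "n2c": d.n_2c,
                "n4c": d.n_4c,
                "n8c": d.n_8c,
                "n16c": d.n_16c,
            }
        )
    pd.DataFrame(out).to_csv(path, index=False)


def read_ploidy_csv(path) -> list[dict]:
    df = pd.read_csv(path)
    extra = set(df.columns) - {"sample", "genotype", "das", "n2c", "n4c", "n8c", "n16c"}
    if extra:
        raise ValueError(
            f"unsupported ploidy columns {sorted(extra)}; classes above 16C "
            "are not accepted"
        )
    rows = []
    for _, r in df.iterrows():
        rows.append(
            {
                "sample": r["sample"],
                "genotype": r.get("genotype", ""),
                "das": r.get("das", ""),
                "distribution": PloidyDistribution(
                    int(r["n2c"]), int(r["n4c"]), int(r["n8c"]), int(r["n16c"])
                ),
            }
        )
    return rows


def write_counts_tsv(m: CountMatrix, path) -> None:
    out = m.counts.copy()
    out.insert(0, "length_bp", m.lengths)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_counts_tsv(path, groups: pd.Series | None = None) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id", float_precision="round_trip")
    lengths = df["length_bp"]
    counts = df.drop(columns="length_bp")
    if groups is None:
        groups = pd.Series("all", index=counts.columns, name="group")
    return CountMatrix(counts=counts, lengths=lengths, groups=groups)


def write_groups_csv(groups: pd.Series, path) -> None:
    groups.rename_axis("sample").rename("group").to_csv(path)


def read_groups_csv(path) -> pd.Series:
    df = pd.read_csv(path)
    return pd.Series(df["group"].values, index=df["sample"].values, name="group")


def write_profile_csv(profiles: list[KinematicProfile], path) -> None:
    frames = [p.table.assign(genotype=p.genotype) for p in profiles]
    out = pd.concat(frames, ignore_index=True)
    cols = ["genotype"] + [c for c in out.columns if c != "genotype"]
    out[cols].to_csv(path, index=False)


def write_de_csv(result: DEResult, path) -> None:
    out = result.table.copy()
    out.index.name = "gene_id"
    out.to_csv(path)


def write_clusters_csv(cs: ClusterSet, path) -> None:
    rows = []
    for cid, members in enumerate(cs.clusters, start=1):
        for g in members:
            rows.append((g, cid))
    for g in cs.unclustered:
        rows.append((g, 0))  # 0 marks the unclustered remainder
    pd.DataFrame(rows, columns=["gene_id", "cluster_id"]).to_csv(path, index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
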