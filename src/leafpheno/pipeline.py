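"""End-to-end synthetic demo study: simulate, analyze, report.

Reconstructs a two-genotype growth study (a wild-type-like line that
proliferates until 15 DAS against an overexpression-like line arresting
at 10 DAS), plus pavement-cell shape, ploidy and differential-expression
analyses, writing every table as CSV and a plain-text summary report.
Identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from leafpheno import io
from leafpheno.kinematics import kinematic_analysis
from leafpheno.morphometrics import convexity_vs_area
from leafpheno.ploidy import ei_with_ci, endoreduplication_index
from leafpheno.synthetic import (
    growth_preset,
    simulate_counts,
    simulate_growth,
    simulate_ploidy,
    simulate_polygons,
)
from leafpheno.transcriptomics import (
    differential_expression,
    qt_cluster,
    scale_to_depth,
)

__all__ = ["RunConfig", "run_demo"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a demo run; every stochastic step receives a
    seed derived deterministically from ``seed``."""

    seed: int = 0
    out_dir: str = "demo_out"
    genotypes: tuple = ("WT-like", "OE-like")
    noise_cv: float = 0.05
    n_polygons: int = 120
    lobe_amplitude: float = 0.35
    lobe_count: int = 8
    n_nuclei: int = 10_000
    n_genes: int = 2000
    n_per_group: int = 3
    frac_de: float = 0.05
    log2fc_de: float = 2.0
    qt_diameter: float = 0.8
    qt_min_size: int = 15

    def subseed(self, k: int) -> int:
        # independent child streams, stable across runs, below 2**31
        return int(np.random.SeedSequence([self.seed, k]).generate_state(1)[0] % (2**31))


# ploidy mixtures: the arrested genotype endoreduplicates more
_PLOIDY_FRACTIONS = {
    "WT-like": (0.55, 0.30, 0.12, 0.03),
    "OE-like": (0.40, 0.30, 0.20, 0.10),
    "OE-mild": (0.45, 0.30, 0.17, 0.08),
}


def run_demo(config: RunConfig) -> Path:
    """Run the full synthetic study; returns the report directory."""
    out = io.ensure_dir(config.out_dir)
    lines = ["synthetic leaf growth study", "=" * 30, f"seed: {config.seed}", ""]

    # --- growth + kinematics -------------------------------------------------
    series_list, profiles = [], []
    for k, name in enumerate(config.genotypes):
        params = growth_preset(name, noise_cv=config.noise_cv, seed=config.subseed(k))
        series, truth = simulate_growth(params)
        series_list.append(series)
        profile = kinematic_analysis(series)
        profiles.append(profile)
        final_n = profile.table["cell_number"].iloc[-1]
        lines.append(
            f"{name}: true arrest day {params.t_arrest:.0f}, "
            f"estimated proliferation exit {profile.t_exit:.0f} DAS, "
            f"final cell number {final_n:,.0f}"
        )
    io.write_growth_csv(series_list, out / "growth.csv")
    io.write_profile_csv(profiles, out / "kinematic_profiles.csv")
    lines.append("")

    # --- pavement-cell shape -------------------------------------------------
    cells = []
    for k, name in enumerate(config.genotypes):
        polys = simulate_polygons(
            config.n_polygons,
            lobe_amplitude=config.lobe_amplitude,
            lobe_count=config.lobe_count,
            seed=config.subseed(100 + k),
        )
        cells.extend((p, name) for p in polys)
    per_cell, curve = convexity_vs_area(cells)
    per_cell.to_csv(out / "convexity.csv", index=False)
    curve.to_csv(out / "convexity_curve.csv", index=False)
    for name, sub in per_cell.groupby("genotype"):
        lines.append(
            f"{name}: median pavement-cell convexity "
            f"{sub['convexity'].median():.3f} (n={len(sub)})"
        )
    lines.append("")

    # --- ploidy --------------------------------------------------------------
    ploidy_rows = []
    for k, name in enumerate(config.genotypes):
        dist = simulate_ploidy(
            _PLOIDY_FRACTIONS.get(name, _PLOIDY_FRACTIONS["WT-like"]),
            n_nuclei=config.n_nuclei,
            seed=config.subseed(200 + k),
        )
        ploidy_rows.append({"sample": f"{name}-s1", "genotype": name, "das": 16,
                            "distribution": dist})
        ei, (lo, hi) = ei_with_ci(dist, seed=config.subseed(300 + k))
        lines.append(
            f"{name}: endoreduplication index {ei:.3f} "
            f"(95% CI {lo:.3f}-{hi:.3f}, n={dist.total} nuclei)"
        )
    io.write_ploidy_csv(ploidy_rows, out / "ploidy.csv")
    lines.append("")

    # --- differential expression + clustering --------------------------------
    matrix, truth_labels = simulate_counts(
        n_genes=config.n_genes,
        n_per_group=config.n_per_group,
        frac_de=config.frac_de,
        log2fc_de=config.log2fc_de,
        seed=config.subseed(400),
    )
    io.write_counts_tsv(matrix, out / "counts.tsv")
    io.write_groups_csv(matrix.groups, out / "groups.csv")
    result = differential_expression(matrix, "A", "B")
    io.write_de_csv(result, out / "de_results.csv")
    n_true = int(truth_labels.sum())
    called = result.table["significant"].to_numpy()
    tp = int((called & truth_labels).sum())
    lines.append(
        f"differential expression: {result.n_significant} genes called "
        f"(planted {n_true}, recovered {tp})"
    )

    sig = result.significant_genes
    if len(sig) >= config.qt_min_size:
        # profiles over per-sample scaled expression in log space
        scaled = scale_to_depth(matrix)
        profiles_df = np.log2(scaled.loc[sig] + 1.0)
        cs = qt_cluster(profiles_df, diameter=config.qt_diameter,
                        min_size=config.qt_min_size)
        io.write_clusters_csv(cs, out / "clusters.csv")
        sizes = [len(c) for c in cs.clusters]
        lines.append(
            f"QT clustering: {len(cs.clusters)} cluster(s) of sizes {sizes}, "
            f"{len(cs.unclustered)} genes unclustered"
        )
    lines.append("")

    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return out
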