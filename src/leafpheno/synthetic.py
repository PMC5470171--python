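"""Synthetic data with known ground truth for every pipeline input.

The generators emulate the designs of a leaf-growth phenotyping study:

* ``simulate_growth`` — piecewise-exponential leaf growth.  Cell number
  grows exponentially at rate ``r_div`` until proliferation arrest at
  ``t_arrest``; mean cell area then grows exponentially at ``r_exp``
  until maturity at ``t_mature``.  Observed replicate areas are the
  noise-free truth multiplied by lognormal measurement noise, so the
  observation model is unbiased in log space and the true rates are
  piecewise-constant — ideal for validating the kinematic estimators.
* ``simulate_polygons`` — jigsaw-like pavement-cell outlines as radial
  perturbations of a circle; zero lobe amplitude gives convex cells.
* ``simulate_ploidy`` — multinomial nuclei counts over 2C/4C/8C/16C.
* ``simulate_counts`` — negative-binomial RNA-seq count matrices with a
  chosen fraction of genes given a planted fold change in group B.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from leafpheno import config
from leafpheno.kinematics import GrowthSeries
from leafpheno.morphometrics import CellPolygon
from leafpheno.ploidy import PloidyDistribution
from leafpheno.transcriptomics import CountMatrix

__all__ = [
    "GrowthParams",
    "SimTruth",
    "growth_preset",
    "simulate_growth",
    "simulate_polygons",
    "simulate_ploidy",
    "simulate_counts",
]


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the piecewise-exponential leaf growth model.

    ``n0`` initial epidermal cell count; ``r_div`` proliferative division
    rate (cells cell^-1 day^-1); ``t_arrest`` day proliferation stops;
    ``r_exp`` relative cell-expansion rate (day^-1) between arrest and
    ``t_mature``; ``a0`` initial mean cell area (um^2); ``noise_cv``
    lognormal coefficient of variation of area measurements;
    ``n_replicates`` leaves per day; ``days`` the sampled days after
    stratification.
    """

    n0: float = config.GROWTH_BASELINE["n0"]
    r_div: float = config.GROWTH_BASELINE["r_div"]
    t_arrest: float = 15.0
    r_exp: float = config.GROWTH_BASELINE["r_exp"]
    a0: float = config.GROWTH_BASELINE["a0"]
    t_mature: float = config.GROWTH_BASELINE["t_mature"]
    noise_cv: float = config.DEFAULT_NOISE_CV
    n_replicates: int = config.DEFAULT_REPLICATES
    seed: int = 0
    days: tuple = config.DEFAULT_DAYS
    genotype: str = "WT-like"

    def __post_init__(self):
        if self.n0 <= 0 or self.a0 <= 0:
            raise ValueError("n0 and a0 must be positive")
        for name in ("r_div", "r_exp", "noise_cv"):
            val = getattr(self, name)
            if not math.isfinite(val) or val < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if not self.t_arrest < self.t_mature:
            raise ValueError("t_arrest must precede t_mature")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        if len(self.days) < 1:
            raise ValueError("days must be non-empty")


def growth_preset(name: str, **overrides) -> GrowthParams:
    """A named genotype preset ('WT-like', 'OE-like', 'OE-mild')."""
    if name not in config.GROWTH_PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; options: {sorted(config.GROWTH_PRESETS)}"
        )
    params = GrowthParams(genotype=name, **config.GROWTH_PRESETS[name])
    return replace(params, **overrides) if overrides else params


@dataclass(frozen=True)
class SimTruth:
    """Noise-free trajectories and true rates of a simulated genotype.

    ``table`` columns: das, cell_number, cell_area_um2, blade_area_mm2,
    div_rate_per_day, rler_per_day.  The identity
    blade_area = cell_number * cell_area holds exactly at every day.
    """

    params: GrowthParams
    table: pd.DataFrame = field(repr=False)


def _true_trajectories(params: GrowthParams, t: np.ndarray):
    n = params.n0 * np.exp(params.r_div * np.minimum(t, params.t_arrest))
    expansion_time = np.clip(t - params.t_arrest, 0.0, params.t_mature - params.t_arrest)
    a = params.a0 * np.exp(params.r_exp * expansion_time)
    blade_mm2 = n * a * 1e-6
    div = np.where(t < params.t_arrest, params.r_div, 0.0)
    rler = div + np.where(
        (t >= params.t_arrest) & (t < params.t_mature), params.r_exp, 0.0
    )
    return n, a, blade_mm2, div, rler


def simulate_growth(params: GrowthParams) -> tuple[GrowthSeries, SimTruth]:
    """Simulate a replicate growth series plus its noise-free truth.

    Each replicate's blade area and mean cell area are the truth times
    independent lognormal noise exp(noise_cv * z), z ~ N(0, 1);
    deterministic given ``params.seed``.
    """
    t = np.asarray(params.days, dtype=float)
    n, a, blade, div, rler = _true_trajectories(params, t)
    truth = SimTruth(
        params=params,
        table=pd.DataFrame(
            {
                "das": params.days,
                "cell_number": n,
                "cell_area_um2": a,
                "blade_area_mm2": blade,
                "div_rate_per_day": div,
                "rler_per_day": rler,
            }
        ),
    )
    rng = np.random.default_rng(params.seed)
    reps = params.n_replicates
    noise_blade = np.exp(params.noise_cv * rng.standard_normal((len(t), reps)))
    noise_cell = np.exp(params.noise_cv * rng.standard_normal((len(t), reps)))
    rows = pd.DataFrame(
        {
            "genotype": params.genotype,
            "das": np.repeat(params.days, reps),
            "replicate": np.tile(np.arange(1, reps + 1), len(t)),
            "blade_area_mm2": (blade[:, None] * noise_blade).ravel(),
            "mean_cell_area_um2": (a[:, None] * noise_cell).ravel(),
        }
    )
    return GrowthSeries(genotype=params.genotype, data=rows), truth


def simulate_polygons(
    n: int,
    lobe_amplitude: float,
    lobe_count: int,
    seed: int = 0,
    n_vertices: int = 64,
    mean_radius_um: float = 20.0,
    radius_cv: float = 0.3,
) -> list[CellPolygon]:
    """Simulate jigsaw-like pavement-cell outlines.

    Each cell is a radial perturbation of a circle,
    r(theta) = R * (1 + lobe_amplitude * sin(lobe_count * theta + phase)),
    sampled at ``n_vertices`` angles; cell radii R are lognormal around
    ``mean_radius_um`` and phases are uniform.  ``lobe_amplitude = 0``
    yields convex (regular-polygon) outlines.
    """
    if not 0 <= lobe_amplitude < 1:
        raise ValueError("lobe_amplitude must be in [0, 1)")
    if lobe_count < 0:
        raise ValueError("lobe_count must be non-negative")
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    sigma = math.sqrt(math.log(1.0 + radius_cv**2))
    polys = []
    for i in range(n):
        radius = mean_radius_um * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        r = radius * (1.0 + lobe_amplitude * np.sin(lobe_count * theta + phase))
        verts = np.column_stack((r * np.cos(theta), r * np.sin(theta)))
        polys.append(CellPolygon(cell_id=f"cell{i:04d}", vertices=verts))
    return polys


def simulate_ploidy(
    fractions,
    n_nuclei: int = 10_000,
    seed: int = 0,
) -> PloidyDistribution:
    """Multinomial draw of nuclei over the 2C/4C/8C/16C classes."""
    f = np.asarray(fractions, dtype=float)
    if f.shape != (4,):
        raise ValueError("fractions must have 4 entries (2C, 4C, 8C, 16C)")
    if np.any(f < 0) or not math.isclose(f.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("fractions must be non-negative and sum to 1")
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be positive")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_nuclei, f / f.sum())
    return PloidyDistribution(*(int(c) for c in counts))


def simulate_counts(
    n_genes: int = 2000,
    n_per_group: int = 3,
    frac_de: float = 0.05,
    log2fc_de: float = 2.0,
    dispersion: float = 0.1,
    mean_depth: float = 1_000_000.0,
    seed: int = 0,
) -> tuple[CountMatrix, np.ndarray]:
    """Negative-binomial count matrix with planted differential expression.

    Baseline per-gene abundances are lognormal and scaled so each sample's
    expected total is ``mean_depth``.  Exactly ``round(frac_de * n_genes)``
    genes (a seeded random subset) have their group-B mean multiplied by
    2**(+-log2fc_de) with random sign.  Counts are negative-binomial with
    gene-level dispersion ``dispersion`` (Poisson when 0); gene lengths
    are uniform integers in 200..5000 bp.  Returns the matrix and a
    boolean truth vector marking the planted genes.
    """
    if n_genes < 1 or n_per_group < 1:
        raise ValueError("n_genes and n_per_group must be positive")
    if not 0 <= frac_de <= 1:
        raise ValueError("frac_de must be in [0, 1]")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=1.2, size=n_genes)
    base = base / base.sum() * mean_depth

    n_de = int(round(frac_de * n_genes))
    truth = np.zeros(n_genes, dtype=bool)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    truth[de_idx] = True
    signs = rng.choice([-1.0, 1.0], size=n_de)
    mean_b = base.copy()
    mean_b[de_idx] = base[de_idx] * 2.0 ** (signs * log2fc_de)

    def draw(mu, size):
        mu_mat = np.broadcast_to(mu[:, None], (n_genes, size))
        if dispersion == 0:
            return rng.poisson(mu_mat)
        r = 1.0 / dispersion
        p = r / (r + mu_mat)
        return rng.negative_binomial(r, p)

    counts_a = draw(base, n_per_group)
    counts_b = draw(mean_b, n_per_group)
    gene_ids = pd.Index([f"gene{i:05d}" for i in range(n_genes)], name="gene_id")
    samples = [f"A{j+1}" for j in range(n_per_group)] + [
        f"B{j+1}" for j in range(n_per_group)
    ]
    counts = pd.DataFrame(
        np.hstack((counts_a, counts_b)), index=gene_ids, columns=samples
    )
    lengths = pd.Series(
        rng.integers(200, 5001, size=n_genes), index=gene_ids, name="length_bp"
    )
    groups = pd.Series(
        ["A"] * n_per_group + ["B"] * n_per_group, index=samples, name="group"
    )
    matrix = CountMatrix(counts=counts, lengths=lengths, groups=groups)
    return matrix, truth
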