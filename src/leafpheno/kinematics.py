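"""Kinematic analysis of leaf growth.

Kinematic growth analysis infers average cellular rates from organ-level
time series: given daily leaf blade areas A(t) (mm^2) and mean epidermal
cell areas a(t) (um^2), the average cell number is N(t) = A(t)*1e6 / a(t),
the relative leaf expansion rate is RLER(t) = d ln A / dt (day^-1), and
the average cell division rate is D(t) = d ln N / dt
(cells cell^-1 day^-1).  The cell-cycle duration follows as
Tc = ln 2 / D wherever cells still divide, and the proliferation-exit day
t_exit is the day D drops to (approximately) zero and stays there.

Derivatives of noisy log-transformed series are taken by local quadratic
regression over a centred five-day window, the established practice in
leaf kinematics; the window shrinks (to no fewer than three points) at
the series edges and the derivative is the analytic derivative of the
local fit at the centre day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from leafpheno import config

__all__ = [
    "GrowthSeries",
    "KinematicProfile",
    "estimate_cell_number",
    "smooth_log_series",
    "kinematic_analysis",
    "compare_timepoint",
    "delta_delta_ct",
]


@dataclass(frozen=True)
class GrowthSeries:
    """Per-day replicate blade areas and sampled mean cell areas for one
    genotype.

    ``data`` columns: das (int), replicate (int), blade_area_mm2,
    mean_cell_area_um2.  Areas must be strictly positive.
    """

    genotype: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        required = {"das", "replicate", "blade_area_mm2", "mean_cell_area_um2"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"GrowthSeries missing columns: {sorted(missing)}")
        if (self.data["blade_area_mm2"] <= 0).any() or (
            self.data["mean_cell_area_um2"] <= 0
        ).any():
            raise ValueError("areas must be strictly positive")
        object.__setattr__(self, "data", self.data.reset_index(drop=True))

    @property
    def days(self) -> np.ndarray:
        return np.sort(self.data["das"].unique())


@dataclass(frozen=True)
class KinematicProfile:
    """Time-indexed kinematic quantities for one genotype.

    ``table`` columns: das, lnA, lnN, rler_per_day, div_rate_per_day,
    cell_number, cell_area_um2, tc_days (NaN where division has ceased).
    ``t_exit`` is the estimated proliferation-arrest day (NaN if the
    division rate never settles below the threshold).
    """

    genotype: str
    table: pd.DataFrame = field(repr=False)
    t_exit: float
    exit_threshold: float


def estimate_cell_number(blade_area_mm2, mean_cell_area_um2):
    """Average cell number in a leaf: blade area / mean cell area.

    Blade areas are mm^2 and cell areas um^2, hence the explicit 1e6
    conversion.  Accepts scalars or arrays; inputs must be positive.
    """
    a = np.asarray(blade_area_mm2, dtype=float)
    c = np.asarray(mean_cell_area_um2, dtype=float)
    if np.any(a <= 0) or np.any(c <= 0):
        raise ValueError("areas must be strictly positive")
    out = a * 1e6 / c
    return float(out) if out.ndim == 0 else out


def smooth_log_series(days, values, window: int = config.DEFAULT_WINDOW):
    """Smooth ln(values) and estimate d ln(values)/dt by local quadratic
    regression.

    For each day a quadratic is fitted (least squares) to ln(values) over
    a centred window of ``window`` days; at the edges the window shrinks
    but never below three points.  Returns ``(ln_smooth, dln_dt)`` at the
    input days.  Exact for series whose logarithm is quadratic in time.
    """
    t = np.asarray(days, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise ValueError("days and values must be 1-D and equal length")
    if len(np.unique(t)) < 3:
        raise ValueError("need at least 3 distinct days to smooth")
    if np.any(np.diff(t) <= 0):
        raise ValueError("days must be strictly increasing")
    if np.any(v <= 0):
        raise ValueError("values must be strictly positive")
    if window < 3:
        raise ValueError("window must be at least 3")
    ln_v = np.log(v)
    n = len(t)
    half = window // 2
    ln_s = np.empty(n)
    dln = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        # never fit through fewer than 3 points
        while hi - lo < min(3, n):
            lo = max(0, lo - 1)
            hi = min(n, hi + 1)
        tt = t[lo:hi] - t[i]
        deg = 2 if hi - lo > 2 else 1
        coef = np.polynomial.polynomial.polyfit(tt, ln_v[lo:hi], deg)
        ln_s[i] = coef[0]
        dln[i] = coef[1]
    return ln_s, dln


def _exit_day(days: np.ndarray, div_rate: np.ndarray, threshold: float) -> float:
    """Proliferation-exit day: where the smoothed division rate drops to
    half its proliferative plateau (floored at ``threshold``) and stays
    below.

    A symmetric smoothing window turns the true step in D(t) into a ramp
    centred on the breakpoint, so the half-plateau crossing recovers the
    arrest day without the lag an absolute near-zero threshold would
    introduce; the crossing is linearly interpolated between days.
    """
    plateau = float(np.max(div_rate))
    if plateau < threshold:
        return float(days[0])  # never proliferating on the observed window
    level = max(threshold, 0.5 * plateau)
    for i in range(len(days)):
        if np.all(div_rate[i:] <= level):
            if i == 0:
                return float(days[0])
            d_prev, d_here = div_rate[i - 1], div_rate[i]
            frac = (d_prev - level) / (d_prev - d_here)
            return float(days[i - 1] + frac * (days[i] - days[i - 1]))
    return math.nan


def kinematic_analysis(
    series: GrowthSeries,
    window: int = config.DEFAULT_WINDOW,
    exit_threshold: float = config.DEFAULT_EXIT_THRESHOLD,
    replicate_average: str = "mean",
) -> KinematicProfile:
    """Full kinematic analysis of one genotype's growth series.

    Replicates are averaged per day before the log transform
    (``replicate_average="mean"``, the default) or averaged in log space
    (``"geometric"``).  Cell numbers are estimated from the daily mean
    blade and cell areas, both log series are smoothed and differentiated,
    and Tc = ln2/D is reported only where D exceeds ``exit_threshold``.
    """
    if replicate_average not in ("mean", "geometric"):
        raise ValueError("replicate_average must be 'mean' or 'geometric'")
    df = series.data
    if replicate_average == "mean":
        daily = df.groupby("das", sort=True).agg(
            blade_area_mm2=("blade_area_mm2", "mean"),
            mean_cell_area_um2=("mean_cell_area_um2", "mean"),
        )
    else:
        daily = np.exp(
            np.log(df[["blade_area_mm2", "mean_cell_area_um2"]])
            .assign(das=df["das"])
            .groupby("das", sort=True)
            .mean()
        )
    days = daily.index.to_numpy(dtype=float)
    blade = daily["blade_area_mm2"].to_numpy()
    cell_area = daily["mean_cell_area_um2"].to_numpy()
    n_cells = estimate_cell_number(blade, cell_area)

    ln_a, rler = smooth_log_series(days, blade, window=window)
    ln_n, div = smooth_log_series(days, n_cells, window=window)
    tc = np.where(div > exit_threshold, math.log(2) / np.where(div > 0, div, np.nan), np.nan)

    table = pd.DataFrame(
        {
            "das": days.astype(int),
            "lnA": ln_a,
            "lnN": ln_n,
            "rler_per_day": rler,
            "div_rate_per_day": div,
            "cell_number": n_cells,
            "cell_area_um2": cell_area,
            "tc_days": tc,
        }
    )
    t_exit = _exit_day(days, div, exit_threshold)
    return KinematicProfile(
        genotype=series.genotype,
        table=table,
        t_exit=t_exit,
        exit_threshold=exit_threshold,
    )


def compare_timepoint(group_a, group_b):
    """Two-sided Welch t-test between two groups of measurements.

    Returns ``(t, p, mean_a, mean_b, se_a, se_b)`` — the means and
    standard errors are the quantities plotted as averages +/- SE.
    Two groups that are both constant and equal give t=0, p=1 by
    convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    mean_a, mean_b = a.mean(), b.mean()
    se_a = a.std(ddof=1) / math.sqrt(len(a))
    se_b = b.std(ddof=1) / math.sqrt(len(b))
    if se_a == 0 and se_b == 0:
        if mean_a == mean_b:
            return 0.0, 1.0, mean_a, mean_b, se_a, se_b
        t = math.inf if mean_a > mean_b else -math.inf
        return t, 0.0, mean_a, mean_b, se_a, se_b
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), mean_a, mean_b, se_a, se_b


def delta_delta_ct(ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
    """Relative expression fold change by the ddCt method.

    fold = 2^-[(Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl)]
    """
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)
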