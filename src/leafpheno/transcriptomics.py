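"""RNA-seq expression statistics.

Implements the expression-analysis chain of a two-group leaf
transcriptome comparison:

* RPKM (reads per kilobase of exon model per million mapped reads),
* per-sample scaling of counts to a common depth of 10 million reads,
* a beta-binomial weighted proportion test between groups ("Baggerley's
  test"): each sample's gene proportion x_i/n_i is weighted by
  w_i = n_i / (1 + phi*(n_i - 1)) with phi a moment estimate of the
  between-sample overdispersion, and the two weighted group proportions
  are compared with a t-type statistic with Satterthwaite degrees of
  freedom,
* Benjamini-Hochberg FDR adjustment and the significance filter
  (adjusted p < alpha and |log2 fold change| > threshold),
* quality-threshold (QT) clustering of significant-gene expression
  profiles under a Pearson-correlation diameter bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from leafpheno import config

__all__ = [
    "CountMatrix",
    "DEResult",
    "ClusterSet",
    "rpkm",
    "scale_to_depth",
    "baggerley_test",
    "bh_fdr",
    "de_filter",
    "differential_expression",
    "qt_cluster",
]


@dataclass(frozen=True)
class CountMatrix:
    """Gene x sample integer read counts with gene lengths and a
    sample-to-group mapping.

    ``counts``: DataFrame (genes x samples, non-negative); ``lengths``:
    Series of exon-model lengths in bp indexed like the genes;
    ``groups``: Series mapping each sample to exactly one group label.
    """

    counts: pd.DataFrame = field(repr=False)
    lengths: pd.Series = field(repr=False)
    groups: pd.Series = field(repr=False)

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.lengths.index.equals(self.counts.index):
            raise ValueError("lengths index must match the gene index")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group assignment: {sorted(missing)}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def samples_in_group(self, group: str) -> list[str]:
        members = [s for s in self.samples if self.groups[s] == group]
        if not members:
            raise KeyError(f"no samples in group {group!r}")
        return members


@dataclass(frozen=True)
class DEResult:
    """Per-gene differential-expression statistics.

    ``table`` columns: mean_a, mean_b (depth-scaled expression), log2fc,
    statistic, pvalue, padj, significant.  The flag is
    padj < alpha AND |log2fc| > fc_threshold.
    """

    table: pd.DataFrame = field(repr=False)
    group_a: str
    group_b: str
    alpha: float
    fc_threshold: float

    @property
    def significant_genes(self) -> pd.Index:
        return self.table.index[self.table["significant"]]

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


@dataclass(frozen=True)
class ClusterSet:
    """Diameter-constrained expression clusters.

    ``clusters``: list of gene-id lists, largest first; ``diameters``:
    realized max pairwise distance of each cluster; ``unclustered``:
    remaining gene ids.
    """

    clusters: list = field(repr=False)
    diameters: list
    unclustered: list = field(repr=False)
    diameter: float
    min_size: int


def rpkm(m: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase of exon model per million mapped reads.

    RPKM_gs = 1e9 * c_gs / (L_g * T_s) with L_g the gene length in bp and
    T_s the total mapped counts of sample s.
    """
    totals = m.counts.sum(axis=0).to_numpy(dtype=float)
    if (totals <= 0).any():
        raise ValueError("every sample needs at least one mapped read")
    lengths = m.lengths.to_numpy(dtype=float)
    vals = 1e9 * m.counts.to_numpy(dtype=float) / (lengths[:, None] * totals[None, :])
    return pd.DataFrame(vals, index=m.genes, columns=m.samples)


def scale_to_depth(
    m: CountMatrix, target: float = config.DEFAULT_TARGET_DEPTH
) -> pd.DataFrame:
    """Scale each sample's counts so its total equals ``target`` reads."""
    totals = m.counts.sum(axis=0).to_numpy(dtype=float)
    if (totals <= 0).any():
        raise ValueError("every sample needs at least one mapped read")
    vals = m.counts.to_numpy(dtype=float) * (target / totals)[None, :]
    return pd.DataFrame(vals, index=m.genes, columns=m.samples)


def _group_stats(x: np.ndarray, n: np.ndarray, phi: np.ndarray):
    """Weighted group proportion and its variance under the beta-binomial
    weighting w_i = n_i / (1 + phi*(n_i - 1))."""
    w = n[None, :] / (1.0 + phi[:, None] * (n[None, :] - 1.0))
    sw = w.sum(axis=1)
    p_hat = (w * (x / n[None, :])).sum(axis=1) / sw
    var = p_hat * (1.0 - p_hat) / sw
    return p_hat, var


def _moment_terms(x, n):
    """Per-group ingredients of the moment overdispersion estimator.

    With binomial weights, the weighted sum of squares around the pooled
    group proportion has expectation
    p(1-p) * [(K-1) + phi*(N - K - (sum n_i^2 - N)/N)];
    returns the pooled proportion, the standardized sum of squares, and
    the (K-1) / denominator terms (zeroed for genes with no counts, which
    carry no dispersion information).
    """
    big_n = n.sum()
    k = len(n)
    p_tilde = x.sum(axis=1) / big_n
    q = x / n[None, :]
    s = (n[None, :] * (q - p_tilde[:, None]) ** 2).sum(axis=1)
    denom_units = big_n - k - (np.sum(n**2) - big_n) / big_n
    pq = p_tilde * (1.0 - p_tilde)
    with np.errstate(divide="ignore", invalid="ignore"):
        s_std = np.where(pq > 0, s / pq, 0.0)
    informative = pq > 0
    return (
        p_tilde,
        s_std,
        np.where(informative, k - 1.0, 0.0),
        np.where(informative, denom_units, 0.0),
    )


def _moderated_overdispersion(x_a, n_a, x_b, n_b, prior_df):
    """Per-gene beta-binomial overdispersion, moderated across genes.

    The raw per-gene moment estimate phi_raw (pooled over both groups,
    group-specific means) rests on only K_A+K_B-2 residual degrees of
    freedom and is far too noisy to weight a per-gene test.  Because phi
    scales with a gene's abundance (phi ~ gamma * p/(1-p), where gamma is
    the abundance-free squared biological CV), the estimates are pooled
    on the gamma scale: each gene's raw gamma is shrunk toward the
    across-gene mean with ``prior_df`` pseudo-degrees of freedom, in the
    spirit of moderated variance estimators for small RNA-seq designs.
    Returns (gamma_shrunk, residual_df, p_pooled_a, p_pooled_b).
    """
    p_a, s_a, df_a, den_a = _moment_terms(x_a, n_a)
    p_b, s_b, df_b, den_b = _moment_terms(x_b, n_b)
    num = (s_a + s_b) - (df_a + df_b)
    den = den_a + den_b
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    p_all = (x_a.sum(axis=1) + x_b.sum(axis=1)) / (n_a.sum() + n_b.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma_raw = np.where(
            p_all > 0, phi_raw * (1.0 - p_all) / np.where(p_all > 0, p_all, 1.0), 0.0
        )
    informative = (den > 0) & (p_all > 0)
    # mean of the unfloored estimates is ~unbiased for a common gamma
    gamma_pool = max(float(gamma_raw[informative].mean()), 0.0) if informative.any() else 0.0
    resid_df = df_a + df_b
    gamma = (resid_df * gamma_raw + prior_df * gamma_pool) / (resid_df + prior_df)
    return gamma, resid_df, p_a, p_b


def baggerley_test(x_a, n_a, x_b, n_b, prior_df: float = 50.0):
    """Beta-binomial weighted two-group proportion test, per gene.

    Each sample's gene proportion x_i/n_i is weighted by
    w_i = n_i / (1 + phi*(n_i - 1)); the group proportion is the weighted
    mean with variance p(1-p)/sum(w), and the statistic is
    (p_hat_A - p_hat_B) / sqrt(V_A + V_B), referred to a t distribution
    with Satterthwaite degrees of freedom plus ``prior_df`` (the
    moderation strength of the cross-gene overdispersion pooling; see
    ``_moderated_overdispersion``).  phi is floored at zero.

    Parameters
    ----------
    x_a, x_b : arrays (genes x samples) of per-sample gene counts
    n_a, n_b : arrays of per-sample total counts

    Returns
    -------
    (statistic, pvalue) arrays.  Genes with zero counts in both groups
    get statistic 0 and p = 1.
    """
    x_a = np.atleast_2d(np.asarray(x_a, dtype=float))
    x_b = np.atleast_2d(np.asarray(x_b, dtype=float))
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    if x_a.shape[1] != len(n_a) or x_b.shape[1] != len(n_b):
        raise ValueError("per-sample counts and totals have mismatched shapes")
    if len(n_a) < 2 or len(n_b) < 2:
        raise ValueError("need at least 2 samples per group")
    if (n_a <= 0).any() or (n_b <= 0).any():
        raise ValueError("sample totals must be positive")

    gamma, _, p_pool_a, p_pool_b = _moderated_overdispersion(
        x_a, n_a, x_b, n_b, prior_df
    )

    def group(x, n, p_pool):
        # convert the abundance-free gamma back to this group's phi scale
        phi = np.clip(
            gamma * p_pool / np.clip(1.0 - p_pool, 1e-12, None), 0.0, 1.0
        )
        return _group_stats(x, n, phi)

    p_a, v_a = group(x_a, n_a, p_pool_a)
    p_b, v_b = group(x_b, n_b, p_pool_b)

    v_sum = v_a + v_b
    diff = p_a - p_b
    k_a, k_b = len(n_a), len(n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(v_sum > 0, diff / np.sqrt(np.where(v_sum > 0, v_sum, 1.0)), 0.0)
        df = np.where(
            v_sum > 0,
            v_sum**2
            / (v_a**2 / (k_a - 1) + v_b**2 / (k_b - 1) + np.where(v_sum > 0, 0, 1)),
            1.0,
        )
    # both variances zero: identical constants -> no evidence (p=1);
    # different constants -> infinitely strong evidence (p=0)
    degenerate = v_sum == 0
    p = np.where(
        degenerate,
        np.where(diff == 0, 1.0, 0.0),
        2.0 * stats.t.sf(np.abs(t), np.maximum(df + prior_df, 1.0)),
    )
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate & (diff != 0), np.sign(diff) * np.inf, t)
    return t, p


def bh_fdr(pvalues, method: str = "bh"):
    """FDR-adjusted p-values (Benjamini-Hochberg step-up by default,
    ``method="bonferroni"`` for the conservative alternative)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    return multipletests(p, method=key)[1]


def de_filter(
    table: pd.DataFrame,
    alpha: float = config.DEFAULT_ALPHA,
    fc_threshold: float = config.DEFAULT_FC_THRESHOLD,
) -> pd.Series:
    """Significance flag: adjusted p < alpha AND |log2fc| strictly >
    fc_threshold (a gene sitting exactly on the fold-change boundary is
    not called)."""
    return (table["padj"] < alpha) & (table["log2fc"].abs() > fc_threshold)


def differential_expression(
    m: CountMatrix,
    group_a: str,
    group_b: str,
    alpha: float = config.DEFAULT_ALPHA,
    fc_threshold: float = config.DEFAULT_FC_THRESHOLD,
    pseudocount: float = config.DEFAULT_PSEUDOCOUNT,
    target_depth: float = config.DEFAULT_TARGET_DEPTH,
    fdr_method: str = "bh",
) -> DEResult:
    """Two-group differential expression: proportion test on raw counts,
    fold changes on depth-scaled expression, FDR filter.

    The proportion test uses raw counts with per-sample totals
    (proportions are depth-free); the reported group means and the
    log2 fold change log2((mean_B + c)/(mean_A + c)) use counts scaled to
    ``target_depth`` with pseudocount ``c``.
    """
    samples_a = m.samples_in_group(group_a)
    samples_b = m.samples_in_group(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need at least 2 samples per group")

    raw = m.counts
    x_a = raw[samples_a].to_numpy(dtype=float)
    x_b = raw[samples_b].to_numpy(dtype=float)
    n_a = raw[samples_a].sum(axis=0).to_numpy(dtype=float)
    n_b = raw[samples_b].sum(axis=0).to_numpy(dtype=float)
    statistic, pvalue = baggerley_test(x_a, n_a, x_b, n_b)

    scaled = scale_to_depth(m, target=target_depth)
    mean_a = scaled[samples_a].mean(axis=1)
    mean_b = scaled[samples_b].mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "statistic": statistic,
            "pvalue": pvalue,
            "padj": bh_fdr(pvalue, method=fdr_method),
        },
        index=m.genes,
    )
    table["significant"] = de_filter(table, alpha=alpha, fc_threshold=fc_threshold)
    return DEResult(
        table=table,
        group_a=group_a,
        group_b=group_b,
        alpha=alpha,
        fc_threshold=fc_threshold,
    )


def _pearson_distance_matrix(profiles: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between row profiles."""
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(profiles)
    return 1.0 - r


def _grow_candidate(dist: np.ndarray, active: np.ndarray, seed_idx: int, diameter: float):
    """Grow one QT candidate cluster from ``seed_idx`` greedily: repeatedly
    add the active gene whose addition keeps the diameter smallest, while
    the diameter stays within the bound; ties go to the lowest index."""
    members = [seed_idx]
    in_cluster = np.zeros(len(dist), dtype=bool)
    in_cluster[seed_idx] = True
    # max distance from each active point to the current members
    dmax = dist[seed_idx].copy()
    dmax[~active] = np.inf
    dmax[seed_idx] = np.inf
    while True:
        j = int(np.argmin(dmax))  # argmin takes the lowest index on ties
        if not np.isfinite(dmax[j]) or dmax[j] > diameter:
            break
        members.append(j)
        in_cluster[j] = True
        dmax = np.maximum(dmax, dist[j])
        dmax[j] = np.inf
    return members


def qt_cluster(
    profiles: pd.DataFrame,
    diameter: float = config.DEFAULT_QT_DIAMETER,
    min_size: int = config.DEFAULT_QT_MIN_SIZE,
) -> ClusterSet:
    """Quality-threshold clustering of expression profiles.

    Distance is 1 - Pearson correlation of the row profiles (anticorrelated
    profiles are far apart).  For every gene a candidate cluster is grown
    greedily under the ``diameter`` bound; the largest candidate (ties to
    the earliest seed) is extracted, its members removed, and the process
    repeats until the largest candidate falls below ``min_size``.
    Constant profiles (undefined correlation) go to the remainder with a
    warning.  Deterministic for a fixed input order.
    """
    if profiles.shape[1] < 3:
        raise ValueError("profiles need at least 3 conditions")
    values = profiles.to_numpy(dtype=float)
    ids = list(profiles.index)

    constant = values.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant profile(s) have undefined "
            "correlation and were left unclustered",
            stacklevel=2,
        )
    usable = np.flatnonzero(~constant)
    remainder = [ids[i] for i in np.flatnonzero(constant)]

    clusters: list[list[str]] = []
    diameters: list[float] = []
    if len(usable) > 0:
        dist = _pearson_distance_matrix(values[usable])
        np.fill_diagonal(dist, 0.0)
        active = np.ones(len(usable), dtype=bool)
        while active.sum() >= min_size:
            best: list[int] | None = None
            for s in np.flatnonzero(active):
                cand = _grow_candidate(dist, active, int(s), diameter)
                if best is None or len(cand) > len(best):
                    best = cand
            assert best is not None
            if len(best) < min_size:
                break
            sub = dist[np.ix_(best, best)]
            clusters.append([ids[usable[i]] for i in best])
            diameters.append(float(sub.max()))
            active[best] = False
        remainder.extend(ids[usable[i]] for i in np.flatnonzero(active))

    return ClusterSet(
        clusters=clusters,
        diameters=diameters,
        unclustered=remainder,
        diameter=diameter,
        min_size=min_size,
    )
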