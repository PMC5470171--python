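"""Expression statistics: RPKM/scaling formulas, proportion-test
calibration, FDR arithmetic, DE filtering, QT clustering."""

import numpy as np
import pandas as pd
import pytest

from leafpheno.synthetic import simulate_counts
from leafpheno.transcriptomics import (
    CountMatrix,
    baggerley_test,
    bh_fdr,
    de_filter,
    differential_expression,
    qt_cluster,
    rpkm,
    scale_to_depth,
)


def make_matrix(counts, lengths, groups=None):
    genes = [f"g{i}" for i in range(len(counts))]
    samples = [f"s{j}" for j in range(len(counts[0]))]
    if groups is None:
        groups = ["A"] * len(samples)
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        lengths=pd.Series(lengths, index=genes),
        groups=pd.Series(groups, index=samples),
    )


class TestRpkm:
    def test_formula(self):
        # 10 reads on a 1 kb gene in a library of 1e6 reads -> RPKM 10
        m = make_matrix([[10], [999_990]], [1000, 5000])
        assert rpkm(m).iloc[0, 0] == pytest.approx(10.0)

    def test_depth_invariance(self):
        m1 = make_matrix([[10], [999_990]], [1000, 5000])
        m2 = make_matrix([[20], [1_999_980]], [1000, 5000])
        pd.testing.assert_frame_equal(rpkm(m1), rpkm(m2))

    def test_hand_arithmetic(self):
        # 50 reads, 2.5 kb gene, 2e6 total -> 1e9*50/(2500*2e6) = 10
        m = make_matrix([[50], [1_999_950]], [2500, 1000])
        assert rpkm(m).iloc[0, 0] == pytest.approx(10.0)


class TestScaleToDepth:
    def test_identity_at_target(self):
        m = make_matrix([[4_000_000], [6_000_000]], [1000, 1000])
        scaled = scale_to_depth(m)
        np.testing.assert_allclose(scaled.to_numpy().ravel(), [4e6, 6e6])

    def test_half_depth_doubles(self):
        m = make_matrix([[2_000_000], [3_000_000]], [1000, 1000])
        scaled = scale_to_depth(m)
        np.testing.assert_allclose(scaled.to_numpy().ravel(), [4e6, 6e6])

    def test_column_sums_hit_target(self):
        m, _ = simulate_counts(n_genes=200, seed=1)
        scaled = scale_to_depth(m)
        np.testing.assert_allclose(scaled.sum(axis=0), 1e7, rtol=1e-6)


class TestBaggerleyTest:
    def test_identical_proportions_give_null(self):
        x = np.array([[100.0, 200.0, 50.0]])
        n = np.array([1000.0, 2000.0, 500.0])
        t, p = baggerley_test(x, n, x, n)
        assert t[0] == 0.0 and p[0] == 1.0

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(3)
        xa = rng.poisson(100, size=(50, 3)).astype(float)
        xb = rng.poisson(150, size=(50, 3)).astype(float)
        na, nb = xa.sum(0), xb.sum(0)
        t1, p1 = baggerley_test(xa, na, xb, nb)
        t2, p2 = baggerley_test(xb, nb, xa, na)
        np.testing.assert_allclose(t1, -t2)
        np.testing.assert_allclose(p1, p2)

    def test_all_zero_gene(self):
        xa = np.array([[0.0, 0.0], [10.0, 20.0]])
        xb = np.array([[0.0, 0.0], [30.0, 10.0]])
        na = np.array([100.0, 200.0])
        nb = np.array([300.0, 100.0])
        t, p = baggerley_test(xa, na, xb, nb)
        assert t[0] == 0.0 and p[0] == 1.0

    def test_null_type_one_error_calibrated(self):
        # no planted effects: raw-p rejections at 5% should be near 5%
        fractions = []
        for rep in range(5):
            m, _ = simulate_counts(
                n_genes=1000, n_per_group=3, frac_de=0.0, seed=700 + rep
            )
            x = m.counts.to_numpy(float)
            xa, xb = x[:, :3], x[:, 3:]
            _, p = baggerley_test(xa, xa.sum(0), xb, xb.sum(0))
            fractions.append((p < 0.05).mean())
        assert 0.02 < np.mean(fractions) < 0.08

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            baggerley_test(
                np.ones((3, 1)), np.array([10.0]), np.ones((3, 2)), np.array([10.0, 10.0])
            )


class TestBhFdr:
    def test_step_up_by_hand(self):
        # max of p*(m/rank) from the top: all become 0.04
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_fdr([0.123])[0] == pytest.approx(0.123)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_bonferroni_option(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.3], method="bonferroni"), [0.02, 0.6])


class TestDeFilter:
    def test_boundary_is_strict(self):
        table = pd.DataFrame(
            {"padj": [0.04, 0.04, 0.06], "log2fc": [0.75, 0.76, 2.0]}
        )
        flags = de_filter(table)
        assert list(flags) == [False, True, False]

    def test_identical_means_never_flagged(self):
        m = make_matrix(
            [[100, 100, 100, 100]], [1000], groups=["A", "A", "B", "B"]
        )
        res = differential_expression(m, "A", "B")
        assert res.table["log2fc"].iloc[0] == 0.0
        assert not res.table["significant"].iloc[0]

    def test_planted_de_recovery(self):
        m, truth = simulate_counts(
            n_genes=1000, n_per_group=3, frac_de=0.05, log2fc_de=2.0, seed=11
        )
        res = differential_expression(m, "A", "B")
        called = res.table["significant"].to_numpy()
        tp = (called & truth).sum()
        assert tp / truth.sum() >= 0.6
        if called.sum():
            assert (called & ~truth).sum() / called.sum() <= 0.15

    def test_sensitivity_monotone_in_effect_size(self):
        recov = []
        for lfc in (0.5, 1.0, 2.0):
            m, truth = simulate_counts(
                n_genes=800, n_per_group=3, frac_de=0.1, log2fc_de=lfc, seed=21
            )
            res = differential_expression(m, "A", "B")
            called = res.table["significant"].to_numpy()
            recov.append((called & truth).sum() / truth.sum())
        assert recov[0] <= recov[1] <= recov[2]


class TestQtCluster:
    def test_two_opposite_blocks(self):
        base = np.array([1.0, 2.0, 3.0, 2.0])
        rng = np.random.default_rng(1)
        profiles = np.vstack(
            [base + rng.normal(0, 1e-9, 4) for _ in range(20)]
            + [-base + rng.normal(0, 1e-9, 4) for _ in range(20)]
        )
        df = pd.DataFrame(profiles, index=[f"g{i}" for i in range(40)])
        cs = qt_cluster(df, diameter=0.8, min_size=15)
        assert sorted(len(c) for c in cs.clusters) == [20, 20]
        assert all(d <= 1e-6 for d in cs.diameters)
        assert not cs.unclustered

    def test_clusters_satisfy_invariants(self):
        rng = np.random.default_rng(7)
        profiles = rng.normal(size=(60, 5)) + np.repeat(
            rng.normal(0, 2, (4, 1)) * np.arange(5), 15, axis=0
        )
        df = pd.DataFrame(profiles, index=[f"g{i}" for i in range(60)])
        cs = qt_cluster(df, diameter=0.8, min_size=5)
        seen = set()
        for members, diam in zip(cs.clusters, cs.diameters):
            assert len(members) >= 5
            assert diam <= 0.8 + 1e-12
            sub = df.loc[members].to_numpy()
            d = 1 - np.corrcoef(sub)
            assert np.nanmax(d) <= 0.8 + 1e-9
            assert not seen.intersection(members)
            seen.update(members)
        assert seen.isdisjoint(cs.unclustered)
        assert seen.union(cs.unclustered) == set(df.index)

    def test_constant_profile_goes_to_remainder(self):
        profiles = np.vstack([np.ones(4), np.arange(4.0), np.arange(4.0) * 2]).repeat(
            5, axis=0
        )
        df = pd.DataFrame(profiles, index=[f"g{i}" for i in range(15)])
        with pytest.warns(UserWarning, match="constant"):
            cs = qt_cluster(df, diameter=0.8, min_size=2)
        assert all(g in cs.unclustered for g in df.index[profiles.std(axis=1) == 0])

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(30, 4)), index=[f"g{i}" for i in range(30)])
        a = qt_cluster(df, min_size=3)
        b = qt_cluster(df, min_size=3)
        assert a.clusters == b.clusters and a.unclustered == b.unclustered

    def test_short_profiles_rejected(self):
        df = pd.DataFrame(np.ones((20, 2)))
        with pytest.raises(ValueError):
            qt_cluster(df)


def test_count_matrix_validation():
    with pytest.raises(ValueError):
        make_matrix([[-1]], [100])
    with pytest.raises(ValueError):
        make_matrix([[1]], [0])
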