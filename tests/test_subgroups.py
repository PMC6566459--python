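"""Subgroup summaries and per-subgroup test statistics."""

import numpy as np
import pytest
from scipy import stats as sps

import subpoptests as sp
from subpoptests import (
    GeneralSubgroups,
    ModelSpec,
    NestedDesign,
    TrialData,
    disjoint_pvalues,
    general_subgroup_summary,
    inverse_normal_statistics,
    regression_statistic,
    replicate_rng,
    simulate_trial,
    summarize_subgroups,
    t_statistic,
    z_statistic,
)
from subpoptests.subgroups import SubgroupSummary, general_t_statistic


def make_data(y, u, x):
    return TrialData(y=np.asarray(y, float), u=np.asarray(u), x=np.asarray(x, float))


class TestSummaries:
    def test_membership_counts(self):
        d = make_data([1, 2, 3, 4], [1, 1, 0, 0], [0.1, 0.6, 0.4, 0.9])
        s = summarize_subgroups(d, NestedDesign((0.5, 1.0)))
        assert s.nt.tolist() == [1, 2] and s.nc.tolist() == [1, 2]

    def test_degenerate_nesting_gives_identical_summaries(self):
        d = make_data([1, 2, 3, 4], [1, 1, 0, 0], [0.1, 0.2, 0.15, 0.05])
        s = summarize_subgroups(d, NestedDesign((0.3, 0.6, 1.0)))
        for arr in (s.nt, s.nc, s.mean_t, s.var_c):
            assert len(set(np.round(arr, 12))) == 1

    def test_against_brute_force(self, rng):
        n = 30
        d = make_data(rng.normal(size=n), rng.integers(0, 2, n), rng.uniform(size=n))
        design = NestedDesign((0.3, 0.7, 1.0))
        s = summarize_subgroups(d, design)
        for k, q in enumerate(design.thresholds):
            yt = [d.y[i] for i in range(n) if d.x[i] <= q and d.u[i] == 1]
            yc = [d.y[i] for i in range(n) if d.x[i] <= q and d.u[i] == 0]
            assert s.nt[k] == len(yt) and s.nc[k] == len(yc)
            assert s.mean_t[k] == pytest.approx(np.mean(yt))
            # variances use subgroup members only
            assert s.var_t[k] == pytest.approx(np.var(yt, ddof=1))
            assert s.var_c[k] == pytest.approx(np.var(yc, ddof=1))

    def test_counts_monotone_in_threshold(self, alt_data, quartile_design):
        s = summarize_subgroups(alt_data, quartile_design)
        assert (np.diff(s.nt) >= 0).all() and (np.diff(s.nc) >= 0).all()


class TestTStatistic:
    def test_hand_computed_example(self):
        d = make_data([1, 2, 3, 0, 1, 2], [1, 1, 1, 0, 0, 0], [0.1] * 6)
        st = t_statistic(summarize_subgroups(d, NestedDesign((1.0,))))
        assert st.values[0] == pytest.approx(1 / np.sqrt(2 / 3))
        assert st.df[0] == 4

    def test_identical_arms_give_zero(self):
        d = make_data([1, 2, 3, 1, 2, 3], [1, 1, 1, 0, 0, 0], [0.5] * 6)
        st = t_statistic(summarize_subgroups(d, NestedDesign((1.0,))))
        assert st.values[0] == 0.0

    def test_full_population_matches_scipy(self, alt_data):
        st = t_statistic(summarize_subgroups(alt_data, NestedDesign((1.0,))))
        ref = sps.ttest_ind(
            alt_data.y[alt_data.u == 1], alt_data.y[alt_data.u == 0],
            equal_var=True, alternative="greater",
        )
        assert st.values[0] == pytest.approx(ref.statistic)
        assert sps.t.sf(st.values[0], st.df[0]) == pytest.approx(ref.pvalue)

    def test_degenerate_flagged(self):
        d = make_data([1.0, 2.0, 3.0], [1, 0, 0], [0.5] * 3)
        st = t_statistic(summarize_subgroups(d, NestedDesign((1.0,))))
        assert st.degenerate[0] and np.isnan(st.values[0])


class TestZStatistic:
    def test_direct_value(self):
        s = SubgroupSummary(
            thresholds=np.array([1.0]), nt=np.array([100]), nc=np.array([100]),
            mean_t=np.array([0.2]), mean_c=np.array([0.0]),
            var_t=np.array([1.0]), var_c=np.array([1.0]),
        )
        assert z_statistic(s, 1.0, 1.0).values[0] == pytest.approx(0.2 / np.sqrt(0.02))
        # homogeneity: scaling both SDs by c scales the statistic by 1/c
        assert z_statistic(s, 2.0, 2.0).values[0] == pytest.approx(
            z_statistic(s, 1.0, 1.0).values[0] / 2
        )


class TestRegression:
    def test_normal_equations_oracle(self, rng):
        n = 25
        y = rng.normal(size=n)
        u = rng.integers(0, 2, n)
        x = rng.uniform(size=n)
        st = regression_statistic(TrialData(y=y, u=u, x=x), NestedDesign((1.0,)))
        # independent least-squares solve via lstsq on the normal equations
        X = np.column_stack([np.ones(n), u, x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        s2 = resid @ resid / (n - 3)
        cov = s2 * np.linalg.inv(X.T @ X)
        assert st.values[0] == pytest.approx(beta[1] / np.sqrt(cov[1, 1]))
        assert st.df[0] == n - 3
        assert st.information[0] == pytest.approx(1 / cov[1, 1])

    def test_close_to_t_statistic_when_x_uninformative(self):
        # x independent of u and y: the covariate adjustment changes the
        # statistic only by estimation noise
        spec = ModelSpec(shape="linear-decreasing", beta1=0.3, n_per_group=1500)
        d = simulate_trial(spec, 3)
        # remove the prognostic dependence so x is pure noise
        d = TrialData(y=d.y + 0.0, u=d.u, x=np.random.default_rng(1).uniform(size=len(d)))
        des = NestedDesign((1.0,))
        t_reg = regression_statistic(d, des).values[0]
        t_two = t_statistic(summarize_subgroups(d, des)).values[0]
        assert t_reg == pytest.approx(t_two, abs=0.1)

    def test_singular_design_flagged(self):
        d = make_data([1, 2, 3, 4], [1, 1, 0, 0], [0.5] * 4)  # constant x
        st = regression_statistic(d, NestedDesign((1.0,)))
        assert st.degenerate[0]


class TestDisjointInverseNormal:
    def test_partition_and_weights(self, rng):
        n = 200
        d = make_data(rng.normal(size=n), rng.integers(0, 2, n), rng.uniform(size=n))
        des = NestedDesign((0.25, 0.5, 1.0))
        p, w, bad = disjoint_pvalues(d, des)
        s = summarize_subgroups(d, des)
        # subset counts accumulate to the nested cumulative counts
        for k in range(des.K):
            lo = -np.inf if k == 0 else des.thresholds[k - 1]
            m = (d.x > lo) & (d.x <= des.thresholds[k])
            nt = (m & (d.u == 1)).sum()
            nc = (m & (d.u == 0)).sum()
            assert w[k] == pytest.approx(1 / (1 / nt + 1 / nc))
        assert not bad.any()

    def test_balanced_subset_weight(self):
        y = np.arange(40, dtype=float)
        u = np.array([1, 0] * 20)
        x = np.full(40, 0.2)
        p, w, _ = disjoint_pvalues(make_data(y, u, x), NestedDesign((0.5,)))
        assert w[0] == pytest.approx(10.0)

    def test_pvalues_uniform_under_global_null(self):
        spec = ModelSpec(shape="step-decreasing", gamma=0.5, beta2=1.0,
                         n_per_group=30)
        des = NestedDesign((0.5, 1.0))
        ps = []
        for r in range(800):
            p, w, bad = disjoint_pvalues(simulate_trial(spec, replicate_rng(8, r)), des)
            if not bad.any():
                ps.extend(p)
        assert sps.kstest(ps, "uniform").pvalue > 1e-3

    def test_single_stage_reduces_to_t_test(self, rng):
        n = 60
        d = make_data(rng.normal(size=n), rng.integers(0, 2, n), rng.uniform(size=n))
        des = NestedDesign((1.0,))
        p, w, _ = disjoint_pvalues(d, des)
        st = inverse_normal_statistics(p, w)
        assert st.values[0] == pytest.approx(sps.norm.isf(p[0]))
        assert sps.norm.sf(st.values[0]) == pytest.approx(p[0])

    def test_equal_weight_two_stage_algebra(self):
        p = np.array([0.04, 0.2])
        w = np.array([5.0, 5.0])
        st = inverse_normal_statistics(p, w)
        z = sps.norm.isf(p)
        assert st.values[1] == pytest.approx((z[0] + z[1]) / np.sqrt(2))
        assert st.information.tolist() == [5.0, 10.0]

    def test_combination_covariance_structure(self, rng):
        # Cov(C_j, C_k) = sqrt(I_j/I_k) over independent uniform p's
        w = np.array([4.0, 8.0, 6.0])
        B = 20000
        c1 = np.empty(B)
        c3 = np.empty(B)
        for b in range(B):
            st = inverse_normal_statistics(rng.uniform(size=3), w)
            c1[b], c3[b] = st.values[0], st.values[2]
        info = np.cumsum(w)
        assert np.std(c3) == pytest.approx(1.0, abs=0.02)
        assert np.corrcoef(c1, c3)[0, 1] == pytest.approx(
            np.sqrt(info[0] / info[2]), abs=0.02
        )

    def test_boundary_pvalues_warn(self):
        with pytest.warns(RuntimeWarning):
            st = inverse_normal_statistics(np.array([0.0]), np.array([1.0]))
        assert np.isinf(st.values[0])


class TestGeneralSubgroups:
    def test_masks_against_brute_force(self, rng):
        x = rng.uniform(size=100)
        g = GeneralSubgroups(sets=(((0.0, 0.3), (0.6, 0.8)), ((0.2, 0.7),)))
        m = g.membership(x)
        for i in range(100):
            assert m[0, i] == ((0 < x[i] <= 0.3) or (0.6 < x[i] <= 0.8))
            assert m[1, i] == (0.2 < x[i] <= 0.7)

    def test_nested_intersection_equals_inner(self, rng):
        n = 120
        d = make_data(rng.normal(size=n), rng.integers(0, 2, n), rng.uniform(size=n))
        g = GeneralSubgroups(sets=(((-np.inf, 0.4),), ((-np.inf, 0.9),)))
        s = general_subgroup_summary(d, g)
        assert s.nt_int[0, 1] == s.nt[0]
        assert s.var_t_int[0, 1] == pytest.approx(s.var_t[0])

    def test_disjoint_intersection_counts_zero(self, rng):
        n = 80
        d = make_data(rng.normal(size=n), rng.integers(0, 2, n), rng.uniform(size=n))
        g = GeneralSubgroups(sets=(((0.0, 0.5),), ((0.5, 1.0),)))
        s = general_subgroup_summary(d, g)
        assert s.nt_int[0, 1] == 0 and s.nc_int[0, 1] == 0

    def test_general_t_matches_nested_t(self, alt_data):
        g = GeneralSubgroups(sets=(((-np.inf, 0.5),), ((-np.inf, 1.0),)))
        st_g = general_t_statistic(general_subgroup_summary(alt_data, g))
        st_n = t_statistic(summarize_subgroups(alt_data, NestedDesign((0.5, 1.0))))
        np.testing.assert_allclose(st_g.values, st_n.values)


def test_cumulative_t_statistics_positively_correlated_under_null():
    # nested statistics share subjects, the basis of the Sidak conservatism
    B, n = 10_000, 80
    rng = np.random.default_rng(606)
    x = rng.uniform(size=(B, 2 * n))
    y = rng.standard_normal((B, 2 * n))
    u = np.tile(np.repeat([1, 0], n), (B, 1))

    def tstat(q):
        m = x <= q
        st = m & (u == 1)
        sc = m & (u == 0)
        nt, nc = st.sum(1), sc.sum(1)
        mt = (st * y).sum(1) / nt
        mc = (sc * y).sum(1) / nc
        vt = ((st * (y - mt[:, None])) ** 2).sum(1) / (nt - 1)
        vc = ((sc * (y - mc[:, None])) ** 2).sum(1) / (nc - 1)
        pv = ((nt - 1) * vt + (nc - 1) * vc) / (nt + nc - 2)
        return (mt - mc) / np.sqrt(pv * (1 / nt + 1 / nc))

    r = np.corrcoef(tstat(0.5), tstat(1.0))[0, 1]
    assert r > 0.5  # ~sqrt(1/2) under equal variances
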