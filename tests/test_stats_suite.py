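"""Tests for the group-comparison and correlation statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neurotimescales.int_core import IntMap
from neurotimescales.stats_suite import (
    ancova_group_effect,
    anova_oneway_summary,
    bh_fdr,
    chi_square_contingency,
    eta_squared_partial,
    hedges_g,
    hedges_g_from_samples,
    normality_gate,
    spearman_grid,
    voxelwise_group_maps,
    welch_t,
    welch_t_from_samples,
)

# group summaries of ROI INT (seconds): TD vs SZ in the left lateral
# occipital and right postcentral spheres of the reference study
TD_LATOCC = (2.48, 1.15, 55)
SZ_LATOCC = (1.73, 1.19, 39)
TD_POSTCEN = (2.7, 1.45, 55)
SZ_POSTCEN = (1.92, 1.36, 39)


def round_half_up(x, decimals=2):
    return np.floor(np.asarray(x) * 10**decimals + 0.5) / 10**decimals


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t(1.0, 2.0, 10, 1.0, 2.0, 10, tail="one_sided_first_larger")
        assert t == 0.0
        assert p == pytest.approx(0.5)

    def test_published_summary_stats(self):
        t, df, p = welch_t(*TD_LATOCC, *SZ_LATOCC)
        assert t == pytest.approx(3.05, abs=0.01)
        assert df == pytest.approx(80.2, abs=0.1)

    def test_antisymmetry(self):
        t1, df1, _ = welch_t(*TD_LATOCC, *SZ_LATOCC)
        t2, df2, _ = welch_t(*SZ_LATOCC, *TD_LATOCC)
        assert t2 == pytest.approx(-t1)
        assert df2 == pytest.approx(df1)

    def test_raw_samples_reduce_to_summary(self, rng):
        x1, x2 = rng.normal(0, 1, 20), rng.normal(0.5, 2, 15)
        raw = welch_t_from_samples(x1, x2)
        summ = welch_t(
            x1.mean(), x1.std(ddof=1), 20, x2.mean(), x2.std(ddof=1), 15
        )
        np.testing.assert_allclose(raw, summ, rtol=1e-14)

    def test_matches_scipy_on_raw_samples(self, rng):
        x1, x2 = rng.normal(0, 1, 25), rng.normal(0.3, 1.7, 18)
        t, df, p = welch_t_from_samples(x1, x2)
        ref = stats.ttest_ind(x1, x2, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_observed_direction_tail(self):
        _, _, p_neg = welch_t(0.0, 1.0, 10, 1.0, 1.0, 10, tail="one_sided_observed")
        _, _, p_hyp = welch_t(0.0, 1.0, 10, 1.0, 1.0, 10, tail="one_sided_first_larger")
        assert p_neg < 0.5 < p_hyp

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            welch_t(1, 0.0, 10, 2, 1.0, 10)
        with pytest.raises(ValueError):
            welch_t(1, 1.0, 1, 2, 1.0, 10)


class TestHedgesG:
    @pytest.mark.parametrize(
        "g1, g2, expected",
        [(TD_LATOCC, SZ_LATOCC, 0.64), (TD_POSTCEN, SZ_POSTCEN, 0.55)],
    )
    def test_published_effect_sizes(self, g1, g2, expected):
        assert round_half_up(hedges_g(*g1, *g2)) == expected

    def test_equal_means_zero(self):
        assert hedges_g(2.0, 1.0, 12, 2.0, 1.5, 15) == 0.0

    def test_raw_overload(self, rng):
        x1, x2 = rng.normal(1, 1, 30), rng.normal(0, 1, 25)
        assert hedges_g_from_samples(x1, x2) == pytest.approx(
            hedges_g(x1.mean(), x1.std(ddof=1), 30, x2.mean(), x2.std(ddof=1), 25),
            rel=1e-14,
        )


class TestAnovaSummary:
    def test_published_iq_example(self):
        F, df1, df2, p = anova_oneway_summary(
            [112.26, 109.1, 99.41], [14.62, 15.21, 13.34], [55, 30, 39]
        )
        assert (df1, df2) == (2, 121)
        assert F == pytest.approx(9.366, rel=1e-3)

    def test_equal_means_zero_F(self):
        F, *_ = anova_oneway_summary([5, 5, 5], [1, 2, 1.5], [10, 12, 9])
        assert F == 0.0

    def test_two_groups_equals_pooled_t_squared(self, rng):
        x1, x2 = rng.normal(0, 1, 14), rng.normal(0.7, 1, 11)
        F, _, _, p_f = anova_oneway_summary(
            [x1.mean(), x2.mean()],
            [x1.std(ddof=1), x2.std(ddof=1)],
            [x1.size, x2.size],
        )
        t, p_t = stats.ttest_ind(x1, x2, equal_var=True)
        assert F == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-9)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway_summary([1, 2], [1.0, 0.0], [5, 5])


class TestChiSquare:
    def test_published_sex_distribution(self):
        chi2, df, p = chi_square_contingency([[29, 26], [5, 25], [8, 31]])
        assert chi2 == pytest.approx(15.8, abs=0.05)
        assert df == 2
        assert p < 0.001

    def test_proportional_table_is_zero(self):
        chi2, _, _ = chi_square_contingency([[10, 20], [5, 10], [15, 30]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_2x2(self):
        chi2, df, _ = chi_square_contingency([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_contingency([[0, 0], [5, 10]])


class TestEtaSquaredPartial:
    @pytest.mark.parametrize(
        "F, expected", [(5.65, 0.08), (3.31, 0.05), (0.0, 0.0)]
    )
    def test_published_values(self, F, expected):
        assert round_half_up(eta_squared_partial(F, 2, 131)) == expected

    def test_bad_df(self):
        with pytest.raises(ValueError):
            eta_squared_partial(1.0, 0, 10)


def brute_force_bh(p):
    """Literal step-up: q_(i) = min_{j >= i} m * p_(j) / j, capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)
        ]
        adj[idx] = min(1.0, min(candidates))
    return adj


class TestBhFdr:
    # uncorrected one-tailed p values of the 13 TD vs SZ ROI comparisons
    TD_SZ_P = [0.03, 0.06, 0.34, 0.2, 0.02, 0.24, 0.02, 0.45, 0.07, 0.09,
               0.06, 0.001, 0.004]
    TD_SZ_P_FDR = [0.08, 0.11, 0.37, 0.26, 0.07, 0.28, 0.07, 0.45, 0.11,
                   0.13, 0.11, 0.01, 0.03]

    def test_reproduces_printed_fdr_column(self):
        adj = bh_fdr(self.TD_SZ_P)
        np.testing.assert_array_equal(round_half_up(adj), self.TD_SZ_P_FDR)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.3] * 6), 0.3)

    def test_adjusted_at_least_raw_and_capped(self, rng):
        p = rng.uniform(0, 1, 40)
        adj = bh_fdr(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)

    def test_adjusted_values_are_step_up_monotone(self, rng):
        # the sorted adjusted vector is non-decreasing, i.e. the step-up
        # monotonization is already a fixed point of itself
        adj = np.sort(bh_fdr(rng.uniform(0, 1, 15)))
        np.testing.assert_array_equal(
            adj, np.minimum.accumulate(adj[::-1])[::-1]
        )

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            p = rng.uniform(0, 1, int(rng.integers(1, 21)))
            np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])


def make_records(rng, n_per_group=(20, 20, 20), shift=None):
    rows = []
    for g, n in zip(("TD", "ASD", "SZ"), n_per_group):
        for i in range(n):
            rows.append(
                {"group": g, "age": rng.normal(25, 4), "sex": rng.choice(["F", "M"]),
                 "iq": rng.normal(105, 15), "fd_mean": abs(rng.normal(0.1, 0.03))}
            )
    records = pd.DataFrame(rows)
    y = rng.standard_normal(len(records))
    if shift:
        y[records["group"] == "SZ"] += shift
    return y, records


class TestAncova:
    def test_without_covariates_equals_oneway_anova(self, rng):
        y, records = make_records(rng)
        res = ancova_group_effect(y, records, covariates=())
        means, sds, ns = [], [], []
        for g in sorted(records["group"].unique()):
            v = y[records["group"] == g]
            means.append(v.mean()); sds.append(v.std(ddof=1)); ns.append(v.size)
        F, df1, df2, p = anova_oneway_summary(means, sds, ns)
        assert res.statistic == pytest.approx(F, rel=1e-10)
        assert res.df == (df1, df2)
        assert res.p_unc == pytest.approx(p, rel=1e-9)

    def test_covariate_affine_rescaling_invariance(self, rng):
        y, records = make_records(rng)
        res1 = ancova_group_effect(y, records)
        records2 = records.copy()
        records2["age"] = records2["age"] * 12.0 + 7.0
        records2["iq"] = records2["iq"] / 15.0 - 2.0
        res2 = ancova_group_effect(y, records2)
        assert res2.statistic == pytest.approx(res1.statistic, rel=1e-9)
        assert res2.effect == pytest.approx(res1.effect, rel=1e-9)

    def test_matches_pingouin_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        y, records = make_records(rng, shift=0.4)
        data = records.copy()
        data["y"] = y
        data["sex01"] = (data["sex"] == "M").astype(float)
        ref = pingouin.ancova(
            data=data, dv="y", between="group",
            covar=["age", "sex01", "iq", "fd_mean"],
        ).set_index("Source")
        res = ancova_group_effect(y, records)
        assert res.statistic == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert res.p_unc == pytest.approx(ref.loc["group", "p_unc"], rel=1e-6)
        assert res.effect == pytest.approx(ref.loc["group", "np2"], rel=1e-6)

    def test_collinear_design_rejected(self, rng):
        y, records = make_records(rng)
        records["iq2"] = records["iq"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            ancova_group_effect(
                y, records, covariates=("age", "iq", "iq2")
            )

    def test_null_type_one_error_and_uniform_p(self):
        rng = np.random.default_rng(42)
        n_sim = 1000
        pvals = []
        for _ in range(n_sim):
            y, records = make_records(rng, n_per_group=(15, 15, 15))
            pvals.append(ancova_group_effect(y, records).p_unc)
        pvals = np.asarray(pvals)
        rate = (pvals < 0.05).mean()
        ci = 2.576 * np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < ci
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3

    def test_power_exceeds_null_rate(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(200):
            y, records = make_records(rng, n_per_group=(15, 15, 15), shift=0.5)
            hits += ancova_group_effect(y, records).p_unc < 0.05
        assert hits / 200 > 0.2

    def test_small_groups_rejected(self, rng):
        y, records = make_records(rng, n_per_group=(2, 10, 10))
        with pytest.raises(ValueError):
            ancova_group_effect(y, records)


class TestSpearmanGrid:
    def _grids(self, x, y):
        roi = pd.DataFrame({"roi1": x})
        clin = pd.DataFrame({"m1": y})
        return spearman_grid(roi, clin)

    def test_monotone_increasing_is_one(self):
        out = self._grids([1, 2, 3, 4, 5], [2, 4, 9, 16, 30])
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_monotone_decreasing_is_minus_one(self):
        out = self._grids([1, 2, 3, 4, 5], [5, 3, 2, 1, 0])
        assert out["rho"].iloc[0] == pytest.approx(-1.0)

    def test_ties_match_average_rank_oracle(self):
        x, y = [1, 2, 2, 3], [1, 2, 3, 4]
        # brute-force oracle: Pearson correlation of average ranks
        rx = pd.Series(x).rank(method="average")
        ry = pd.Series(y).rank(method="average")
        expected = np.corrcoef(rx, ry)[0, 1]
        out = self._grids(x, y)
        assert out["rho"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_too_few_pairs_marked_missing(self):
        roi = pd.DataFrame({"roi1": [1.0, 2.0, np.nan, np.nan, np.nan]})
        clin = pd.DataFrame({"m1": [1.0, 2.0, 3.0, 4.0, 5.0]})
        out = spearman_grid(roi, clin)
        assert np.isnan(out["rho"].iloc[0])
        assert out["n"].iloc[0] == 2

    def test_fdr_within_each_group_family(self, rng):
        n = 24
        roi = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        clin = pd.DataFrame(rng.normal(size=(n, 2)), columns=["m1", "m2"])
        groups = pd.Series(["ASD"] * 12 + ["SZ"] * 12)
        out = spearman_grid(roi, clin, groups=groups)
        for grp in ("ASD", "SZ"):
            sub = out[out["group"] == grp]
            np.testing.assert_allclose(
                sub["p_fdr"].to_numpy(), bh_fdr(sub["p_unc"].to_numpy()), atol=1e-12
            )


class TestNormalityGate:
    def test_normal_draws_usually_pass(self):
        passed = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(500)
            _, p, normal = normality_gate(x)
            passed += normal
        assert passed >= 90

    def test_exponential_draws_fail(self):
        failures = 0
        for seed in range(100):
            x = np.random.default_rng(seed).exponential(size=500)
            _, p, _ = normality_gate(x)
            failures += p < 0.01
        assert failures >= 99

    def test_n_too_small_rejected(self):
        with pytest.raises(ValueError):
            normality_gate([1.0, 2.0])

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            normality_gate([3.0] * 10)


def maps_from_values(values, affine=None):
    affine = np.eye(4) if affine is None else affine
    return [
        IntMap(grid=v, affine=affine, mask=np.ones(v.shape, bool)) for v in values
    ]


class TestVoxelwise:
    def test_planted_blob_recovered_in_cluster_table(self):
        rng = np.random.default_rng(21)
        shape = (14, 14, 14)
        blob = (slice(4, 7), slice(4, 7), slice(4, 7))
        vals = []
        groups = []
        for g, shift in (("TD", 0.0), ("SZ", -2.0)):
            for _ in range(12):
                v = rng.standard_normal(shape)
                if shift:
                    v[blob] += shift
                vals.append(v)
                groups.append(g)
        res = voxelwise_group_maps(maps_from_values(vals), groups)
        tdsz = res.clusters[res.clusters["map"] == "TD>SZ"]
        assert len(tdsz) >= 1
        peak = tdsz.sort_values("peak_stat").iloc[-1]
        assert 4 <= peak["peak_x_mm"] <= 6  # identity affine: mm == voxel
        assert 4 <= peak["peak_y_mm"] <= 6
        assert 4 <= peak["peak_z_mm"] <= 6

    def test_null_suprathreshold_fraction_near_alpha(self):
        rng = np.random.default_rng(3)
        shape = (30, 30, 30)
        vals = [rng.standard_normal(shape) for _ in range(24)]
        groups = ["TD"] * 8 + ["ASD"] * 8 + ["SZ"] * 8
        res = voxelwise_group_maps(maps_from_values(vals), groups, threshold_p=0.001)
        frac = np.mean(res.f_map[res.mask] > res.f_threshold)
        n_vox = int(res.mask.sum())
        tol = 4 * np.sqrt(0.001 * 0.999 / n_vox)
        assert abs(frac - 0.001) < tol

    def test_single_subject_group_rejected(self):
        vals = [np.zeros((4, 4, 4)) + np.random.default_rng(i).normal(size=(4, 4, 4))
                for i in range(3)]
        with pytest.raises(ValueError, match=">= 2 subjects"):
            voxelwise_group_maps(maps_from_values(vals), ["TD", "TD", "SZ"])

    def test_grid_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        a = maps_from_values([rng.standard_normal((4, 4, 4)) for _ in range(2)])
        b = maps_from_values([rng.standard_normal((5, 5, 5)) for _ in range(2)])
        with pytest.raises(ValueError, match="share grid"):
            voxelwise_group_maps(a + b, ["TD", "TD", "SZ", "SZ"])
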