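from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from methylaging import cohort_stats as cs
from methylaging.io_formats import CohortTable


def permutation_mw_pvalue(a, b):
    """Full-enumeration oracle for the two-sided Mann-Whitney p-value."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1 = len(a)
    mid = n1 * len(b) / 2

    def u_of(x, y):
        d = x[:, None] - y[None, :]
        return (d > 0).sum() + 0.5 * (d == 0).sum()

    obs = abs(u_of(a, b) - mid)
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        total += 1
        if abs(u_of(pooled[mask], pooled[~mask]) - mid) >= obs - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_extreme_separation_exact_p(self):
        u, p = cs.mann_whitney([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets_p_one(self):
        _, p = cs.mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_full_permutation(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 6), rng.integers(2, 6)
        a = rng.integers(0, 8, n1).astype(float)  # integer values force ties
        b = rng.integers(0, 8, n2).astype(float)
        _, p = cs.mann_whitney(a, b)
        assert p == pytest.approx(permutation_mw_pvalue(a, b), abs=1e-12)

    def test_large_sample_close_to_scipy(self, rng):
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1, 35)
        u, p = cs.mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided")
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cs.mann_whitney([], [1.0])


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert cs.benjamini_hochberg([0.03]) == pytest.approx([0.03])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(cs.benjamini_hochberg([0.2] * 5), [0.2] * 5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_definition(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 30))
        m = len(p)
        order = np.argsort(p)
        brute = np.empty(m)
        for rank_idx, i in enumerate(order):
            js = order[rank_idx:]
            brute[i] = min(
                1.0,
                min(p[j] * m / (list(order).index(j) + 1) for j in js),
            )
        np.testing.assert_allclose(cs.benjamini_hochberg(p), brute, atol=1e-12)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.random(50)
        q = cs.benjamini_hochberg(p)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cs.benjamini_hochberg([0.5, 1.2])


class TestPartialPearson:
    def test_orthogonal_control_equals_plain_pearson(self, rng):
        n = 200
        z = rng.normal(size=n)
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        # orthogonalize x and y against z exactly
        for v in (x, y):
            v -= np.polyval(np.polyfit(z, v, 1), z)
        r_partial = cs.partial_pearson(x, y, z)
        r_plain = np.corrcoef(x, y)[0, 1]
        assert r_partial == pytest.approx(r_plain, abs=1e-10)

    def test_y_equal_control_rejected(self, rng):
        z = rng.normal(size=20)
        with pytest.raises(ValueError, match="residual"):
            cs.partial_pearson(rng.normal(size=20), z.copy(), z)

    @pytest.mark.parametrize("seed", range(4))
    def test_residual_method_matches_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        x, y, z = rng.normal(size=(3, 50))
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        closed = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        assert cs.partial_pearson(x, y, z) == pytest.approx(closed, abs=1e-10)


class TestAssociationOutliers:
    def test_perfect_line_no_flags(self):
        x = pd.Series(np.arange(10.0))
        assert len(cs.association_outliers(x, 2 * x + 1)) == 0

    def test_planted_displaced_point_flagged(self, rng):
        x = pd.Series(np.linspace(0, 10, 50))
        y = 3 * x + 2 + pd.Series(rng.normal(0, 0.1, 50))
        y.iloc[17] += 10 * 0.1 * 10  # displaced far beyond the noise scale
        flagged = cs.association_outliers(x, y)
        assert list(flagged) == [17]

    def test_flags_invariant_to_affine_rescaling(self, rng):
        x = pd.Series(rng.normal(size=60))
        y = 2 * x + pd.Series(rng.normal(0, 1, 60))
        base = set(cs.association_outliers(x, y))
        scaled = set(cs.association_outliers(x, 5.0 * y - 3.0))
        assert base == scaled

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cs.association_outliers(pd.Series([1.0, 1.0, 1.0]), pd.Series([1.0, 2.0, 3.0]))


class TestMedianStratify:
    def test_four_values(self):
        labels = cs.median_stratify(pd.Series([1, 2, 3, 4], index=list("abcd")))
        assert labels.tolist() == ["Low", "Low", "High", "High"]

    def test_all_equal_all_low(self):
        assert (cs.median_stratify(pd.Series([2.0] * 5)) == "Low").all()

    def test_balanced_split_without_ties(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 40))
            values = pd.Series(rng.normal(size=n))
            counts = cs.median_stratify(values).value_counts()
            assert abs(counts.get("High", 0) - counts.get("Low", 0)) <= 1


class TestAnova:
    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1, 15)
        f, p_f = cs.one_way_anova([a, b])
        t, p_t = sps.ttest_ind(a, b)
        assert f == pytest.approx(t**2, abs=1e-10)
        assert p_f == pytest.approx(p_t, abs=1e-10)

    def test_identical_groups_f_zero(self):
        g = [1.0, 2.0, 3.0]
        f, p = cs.one_way_anova([g, g, g])
        assert f == pytest.approx(0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_three_groups(self):
        # grand mean 5; SSB = 3*(3-5)^2 + 3*(5-5)^2 + 3*(7-5)^2 = 24
        # SSW = 2 + 2 + 2 = 6; F = (24/2) / (6/6) = 12
        groups = [[2, 3, 4], [4, 5, 6], [6, 7, 8]]
        f, p = cs.one_way_anova(groups)
        assert f == pytest.approx(12.0, abs=1e-10)
        assert p == pytest.approx(sps.f.sf(12.0, 2, 6), abs=1e-12)

    def test_degenerate_zero_within_variance_rejected(self):
        with pytest.raises(ValueError):
            cs.one_way_anova([[1.0, 1.0], [2.0, 2.0]])


def make_cohort(n, rng, carriers=None, genes=("GENEA", "GENEB")):
    idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    df = pd.DataFrame(
        {
            "age_years": rng.uniform(30, 80, n),
            "os_months": rng.exponential(24, n),
            "os_event": rng.integers(0, 2, n),
        },
        index=idx,
    )
    for g in genes:
        df[f"{g}_mut"] = 0
        if carriers and g in carriers:
            df.loc[carriers[g], f"{g}_mut"] = 1
    return CohortTable(df)


class TestMutationScreen:
    def test_below_carrier_threshold_screened_out(self, rng):
        cohort = make_cohort(30, rng, carriers={"GENEA": ["s0", "s1"]})
        values = pd.Series(rng.normal(size=30), index=cohort.table.index)
        out = cs.mutation_screen(cohort, values)
        assert out.loc["GENEA", "screened_out"]
        assert np.isnan(out.loc["GENEA", "adj_p"])

    def test_planted_deficit_detected_decoys_not(self, rng):
        n = 120
        carriers = {
            "GENEA": [f"s{i}" for i in range(25)],
            "GENEB": [f"s{i}" for i in range(40, 52)],
        }
        cohort = make_cohort(n, rng, carriers=carriers)
        values = pd.Series(rng.normal(0, 1, n), index=cohort.table.index)
        values.iloc[:25] -= 2.5  # GENEA carriers get a strong deficit
        out = cs.mutation_screen(cohort, values)
        assert out.loc["GENEA", "adj_p"] < 0.05
        assert out.loc["GENEB", "adj_p"] > 0.05

    def test_null_gene_pvalues_roughly_uniform(self):
        # repeated null screens: carrier labels independent of the values
        pvals = []
        for seed in range(150):
            rng = np.random.default_rng(seed)
            cohort = make_cohort(
                40, rng, carriers={"GENEA": [f"s{i}" for i in rng.choice(40, 10, replace=False)]},
                genes=("GENEA",),
            )
            values = pd.Series(rng.normal(size=40), index=cohort.table.index)
            out = cs.mutation_screen(cohort, values)
            pvals.append(out.loc["GENEA", "p"])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        km = cs.km_estimate([5, 8, 12], [0, 0, 0])
        assert km.empty  # no event times -> step function identically 1
        assert cs.km_survival_at(km, 100) == 1.0

    def test_all_events_closed_form(self):
        km = cs.km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(km["survival"], [2 / 3, 1 / 3, 0.0])

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, 40)
        km = cs.km_estimate(t, np.ones(40, int))
        for row in km.itertuples():
            assert row.survival == pytest.approx(np.mean(t > row.time))

    def test_matches_hand_product_limit_with_censoring(self):
        # times 2(e) 3(c) 5(e) 7(e) 9(c):
        # S(2) = 4/5; S(5) = 4/5 * 2/3; S(7) = 4/5 * 2/3 * 1/2
        km = cs.km_estimate([2, 3, 5, 7, 9], [1, 0, 1, 1, 0])
        np.testing.assert_allclose(
            km["survival"], [4 / 5, 4 / 5 * 2 / 3, 4 / 5 * 2 / 3 * 1 / 2], atol=1e-12
        )

    def test_agrees_with_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        t = rng.exponential(20, 60)
        e = rng.integers(0, 2, 60)
        if e.sum() == 0:
            e[0] = 1
        km = cs.km_estimate(t, e)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        for row in km.itertuples():
            assert row.survival == pytest.approx(
                float(kmf.survival_function_at_times(row.time).iloc[0]), abs=1e-10
            )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            cs.km_estimate([-1, 2], [1, 1])


class TestLogRank:
    def test_identical_groups_chi2_zero(self):
        t, e = [2, 4, 6, 8], [1, 0, 1, 1]
        chi2, p = cs.logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_example(self):
        # A: 1(e) 3(e) 5(c); B: 2(e) 4(e) 6(e). Hand tables:
        # t=1: O-E = 1 - 3/6,   V = (3/6)(3/6)(5)/5      = 1/4
        # t=2: O-E = 0 - 2/5,   V = (2/5)(3/5)(4)/4      = 6/25
        # t=3: O-E = 1 - 2/4,   V = (2/4)(2/4)(3)/3      = 1/4
        # t=4: O-E = 0 - 1/3,   V = (1/3)(2/3)(2)/2      = 2/9
        # t=6: risk set has one subject -> zero variance contribution
        chi2, p = cs.logrank_test([1, 3, 5], [1, 1, 0], [2, 4, 6], [1, 1, 1])
        sum_ome = 0.5 - 0.4 + 0.5 - 1 / 3
        sum_v = 0.25 + 6 / 25 + 0.25 + 2 / 9
        assert chi2 == pytest.approx(sum_ome**2 / sum_v, abs=1e-10)
        assert p == pytest.approx(sps.chi2.sf(sum_ome**2 / sum_v, 1), abs=1e-12)

    def test_agrees_with_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        ta, tb = rng.exponential(10, 50), rng.exponential(20, 50)
        ea, eb = rng.integers(0, 2, 50), rng.integers(0, 2, 50)
        ea[0] = eb[0] = 1
        chi2, p = cs.logrank_test(ta, ea, tb, eb)
        ref = lifelines.statistics.logrank_test(ta, tb, ea, eb)
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
        assert p == pytest.approx(ref.p_value, abs=1e-8)

    def test_invariant_to_group_swap(self, rng):
        ta, tb = rng.exponential(10, 30), rng.exponential(25, 30)
        ea = np.ones(30, int)
        chi2_ab, _ = cs.logrank_test(ta, ea, tb, ea)
        chi2_ba, _ = cs.logrank_test(tb, ea, ta, ea)
        assert chi2_ab == pytest.approx(chi2_ba, abs=1e-10)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cs.logrank_test([1, 2], [0, 0], [3, 4], [0, 0])


class TestTruncateFollowup:
    def test_administrative_censoring_at_horizon(self):
        t, e = cs.truncate_followup([5, 18, 30], [1, 0, 1], horizon=18)
        np.testing.assert_allclose(t, [5, 18, 18])
        np.testing.assert_array_equal(e, [1, 0, 0])
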