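"""Effect sizes, exact rank tests, correlations, group comparisons."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import natriq as nq
from natriq.errors import (
    DomainError,
    InputError,
    SingularFitError,
    UndefinedStatisticError,
)


class TestCohensD:
    def test_wm_summary_reproduces_medium_effect(self):
        """Pooled-SD d on the WM group summaries gives -0.61."""
        d = nq.cohens_d(30.0, 3.2, 24, 31.6, 1.6, 19)
        assert d == pytest.approx(-0.61, abs=0.005)

    def test_gm_summary_value(self):
        d = nq.cohens_d(34.4, 2.1, 24, 37.9, 1.4, 19)
        assert d == pytest.approx(-1.92, abs=0.005)

    def test_identical_groups_give_zero(self):
        assert nq.cohens_d(30.0, 2.0, 10, 30.0, 2.0, 12) == 0.0

    def test_zero_pooled_sd_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            nq.cohens_d(30.0, 0.0, 10, 31.0, 0.0, 12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        m1=st.floats(-50, 50), m2=st.floats(-50, 50),
        s1=st.floats(0.1, 10), s2=st.floats(0.1, 10),
        n1=st.integers(2, 40), n2=st.integers(2, 40),
        scale=st.floats(0.1, 10), shift=st.floats(-100, 100),
    )
    def test_antisymmetry_and_affine_invariance(self, m1, m2, s1, s2, n1, n2, scale, shift):
        d = nq.cohens_d(m1, s1, n1, m2, s2, n2)
        swapped = nq.cohens_d(m2, s2, n2, m1, s1, n1)
        assert swapped == pytest.approx(-d, rel=1e-12, abs=1e-12)
        rescaled = nq.cohens_d(
            scale * m1 + shift, scale * s1, n1, scale * m2 + shift, scale * s2, n2
        )
        assert rescaled == pytest.approx(d, rel=1e-9, abs=1e-9)


class TestCoefficientOfVariation:
    @pytest.mark.parametrize(
        "mean,sd,value,label",
        [
            (34.4, 2.1, 6.10, "6%"),
            (30.0, 3.2, 10.67, "11%"),
            (37.9, 1.4, 3.69, "4%"),
            (31.6, 1.6, 5.06, "5%"),
        ],
    )
    def test_group_summary_cvs(self, mean, sd, value, label):
        assert nq.coefficient_of_variation(mean, sd) == pytest.approx(value, abs=0.01)
        assert nq.cv_percent_label(mean, sd) == label

    def test_scale_invariance(self):
        assert nq.coefficient_of_variation(7 * 34.4, 7 * 2.1) == pytest.approx(
            nq.coefficient_of_variation(34.4, 2.1)
        )

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(DomainError):
            nq.coefficient_of_variation(0.0, 1.0)


def _enumeration_mw(x, y):
    """Full-permutation oracle for the exact two-sided Mann-Whitney p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n, n_x = len(pooled), len(x)
    ranks = sps.rankdata(pooled)
    r_obs = ranks[:n_x].sum()
    u_obs = r_obs - n_x * (n_x + 1) / 2
    sums = [ranks[list(idx)].sum() for idx in itertools.combinations(range(n), n_x)]
    sums = np.asarray(sums)
    tol = 1e-9
    p_le = np.mean(sums <= r_obs + tol)
    p_ge = np.mean(sums >= r_obs - tol)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


class TestExactMannWhitney:
    def test_textbook_example(self):
        """{1,2} vs {3,4}: U=0 and p=1/3 from the 6 equally likely labelings."""
        u, p = nq.exact_mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_samples_give_p_one(self):
        u, p = nq.exact_mann_whitney([5, 6, 7], [5, 6, 7])
        assert p == 1.0

    @pytest.mark.parametrize(
        "values",
        [
            (1.0, 2.5, 3.0, 4.2, 5.1, 6.0, 7.7, 8.8, 9.9),  # tie-free
            (1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 5.0, 5.0),  # ties
            (2.0, 2.0, 2.0, 2.0, 7.0, 7.0, 7.0, 1.0, 9.0),  # heavy ties
        ],
    )
    def test_matches_enumeration_oracle_all_splits(self, values):
        """For every split of a 9-value multiset, the shift-algorithm p
        equals the full-enumeration permutation p."""
        values = np.asarray(values)
        n = len(values)
        for n_x in range(1, n):
            for idx in itertools.combinations(range(n), n_x):
                x = values[list(idx)]
                y = np.delete(values, list(idx))
                u_dp, p_dp = nq.exact_mann_whitney(x, y)
                u_or, p_or = _enumeration_mw(x, y)
                assert u_dp == pytest.approx(u_or, abs=1e-9)
                assert p_dp == pytest.approx(p_or, abs=1e-12)

    def test_matches_scipy_without_ties(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, rng.integers(3, 12))
            y = rng.normal(0.5, 1, rng.integers(3, 12))
            _, p = nq.exact_mann_whitney(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_p_in_unit_interval(self, rng):
        for _ in range(20):
            x = rng.integers(0, 4, rng.integers(2, 8)).astype(float)
            y = rng.integers(0, 4, rng.integers(2, 8)).astype(float)
            _, p = nq.exact_mann_whitney(x, y)
            assert 0 < p <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            nq.exact_mann_whitney([], [1, 2])

    def test_cap_on_combined_size(self, rng):
        with pytest.raises(InputError):
            nq.exact_mann_whitney(rng.normal(size=40), rng.normal(size=40))

    def test_supports_study_sample_sizes(self, rng):
        """Combined n = 43 (24 + 19) is inside the exact regime."""
        x = rng.normal(34.4, 2.1, 24)
        y = rng.normal(37.9, 1.4, 19)
        _, p = nq.exact_mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestSpearman:
    def test_monotone_limits(self):
        x = np.arange(10.0)
        r, _ = nq.spearman_direct(x, x**3 + 1)
        assert r == pytest.approx(1.0)
        r, _ = nq.spearman_direct(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r, p = nq.spearman_direct(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        r_oracle = np.corrcoef(rx, ry)[0, 1]
        assert r == pytest.approx(r_oracle, abs=1e-12)
        ref = sps.spearmanr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_rank_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            nq.spearman_direct([1, 1, 1], [1, 2, 3])


class TestSpearmanPartial:
    def test_reduces_to_direct_with_rank_orthogonal_covariate(self):
        x = np.arange(8.0)
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0, 8.0, 7.0])
        # find a covariate whose ranks are orthogonal to both rank vectors
        rx = sps.rankdata(x) - 4.5
        ry = sps.rankdata(y) - 4.5
        z = None
        for perm in itertools.permutations(range(8)):
            rz = np.asarray(perm, float) + 1 - 4.5
            if abs(rz @ rx) < 1e-9 and abs(rz @ ry) < 1e-9:
                z = np.asarray(perm, float)
                break
        assert z is not None
        r_partial, _ = nq.spearman_partial(x, y, z)
        r_direct, _ = nq.spearman_direct(x, y)
        assert r_partial == pytest.approx(r_direct, abs=1e-12)

    def test_covariate_equal_to_variable_is_degenerate(self):
        x = np.arange(6.0)
        y = np.array([3.0, 1.0, 2.0, 6.0, 4.0, 5.0])
        with pytest.raises(UndefinedStatisticError):
            nq.spearman_partial(x, y, y)

    def test_matches_residual_regression_oracle(self, rng):
        """First-order formula equals correlating rank residuals."""
        x = rng.normal(size=12)
        y = 0.5 * x + rng.normal(size=12)
        z = 0.3 * x + rng.normal(size=12)
        r, _ = nq.spearman_partial(x, y, z)
        rx, ry, rz = (sps.rankdata(v) for v in (x, y, z))
        rz_c = np.column_stack([np.ones(12), rz])
        res_x = rx - rz_c @ np.linalg.lstsq(rz_c, rx, rcond=None)[0]
        res_y = ry - rz_c @ np.linalg.lstsq(rz_c, ry, rcond=None)[0]
        oracle = np.corrcoef(res_x, res_y)[0, 1]
        assert r == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(size=15)
        y = 0.6 * x + rng.normal(size=15)
        z = rng.normal(size=15)
        r, p = nq.spearman_partial(x, y, z)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z", method="spearman")
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)


class TestAncova:
    def test_recovers_group_difference_with_null_covariate(self):
        rng = np.random.default_rng(77)
        n = 2000
        group = np.array(["a"] * n + ["b"] * n)
        cov = rng.normal(size=2 * n)
        values = np.where(group == "b", 2.5, 0.0) + rng.normal(0, 1, 2 * n)
        diff, p = nq.ancova_compare(values, group, cov)
        se = math.sqrt(2 / n)
        assert abs(diff - 2.5) < 3 * se
        assert p < 1e-10

    def test_adjusts_for_covariate_imbalance(self):
        """With value = covariate and groups offset only through the
        covariate, the adjusted difference is ~0."""
        rng = np.random.default_rng(78)
        n = 500
        group = np.array(["a"] * n + ["b"] * n)
        cov = np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)])
        values = 1.5 * cov + rng.normal(0, 0.1, 2 * n)
        diff, _ = nq.ancova_compare(values, group, cov)
        assert abs(diff) < 0.1

    def test_constant_covariate_rejected(self):
        with pytest.raises(SingularFitError):
            nq.ancova_compare([1, 2, 3, 4], ["a", "a", "b", "b"], [5, 5, 5, 5])

    def test_single_group_rejected(self):
        with pytest.raises(InputError):
            nq.ancova_compare([1, 2, 3, 4], ["a"] * 4, [1, 2, 3, 4])


class TestRecoverySplit:
    def test_dichotomy(self):
        assert nq.recovery_split(8) == "recovered"
        for g in range(1, 8):
            assert nq.recovery_split(g) == "non_recovered"

    @pytest.mark.parametrize("g", [0, 9, -1])
    def test_out_of_range(self, g):
        with pytest.raises(DomainError):
            nq.recovery_split(g)


class TestCompareGroups:
    def _toy_table(self):
        return pd.DataFrame({
            "id": [f"s{i}" for i in range(6)],
            "group": ["patient"] * 3 + ["control"] * 3,
            "gm_tsc": [33.0, 35.0, 34.0, 38.0, 37.0, 39.0],
        })

    def test_fields_match_hand_computation(self):
        t = self._toy_table()
        c = nq.compare_groups(t, "gm_tsc")
        vp = np.array([33.0, 35.0, 34.0])
        vc = np.array([38.0, 37.0, 39.0])
        assert c.n_p == 3 and c.n_c == 3
        assert c.mean_p == pytest.approx(vp.mean())
        assert c.sd_c == pytest.approx(vc.std(ddof=1))
        assert c.median_p == 34.0
        q1, q3 = np.percentile(vp, [25, 75])
        assert c.iqr_p == pytest.approx(q3 - q1)
        assert c.cv_p == pytest.approx(100 * vp.std(ddof=1) / vp.mean())
        assert c.cohens_d == pytest.approx(
            nq.cohens_d(vp.mean(), vp.std(ddof=1), 3, vc.mean(), vc.std(ddof=1), 3)
        )
        # all 20 labelings put the patient ranks at the extreme: p = 2/20
        assert c.mw_p_value == pytest.approx(0.1, abs=1e-12)

    def test_null_case_small_effect(self):
        rng = np.random.default_rng(5)
        t = pd.DataFrame({
            "id": [f"s{i}" for i in range(200)],
            "group": ["patient"] * 100 + ["control"] * 100,
            "gm_tsc": rng.normal(35, 2, 200),
        })
        # subsample to stay inside the exact-MW regime
        t = t.iloc[list(range(20)) + list(range(100, 120))]
        c = nq.compare_groups(t, "gm_tsc")
        assert abs(c.cohens_d) < 1.0
        assert c.mw_p_value > 0.01

    def test_exclusion_list_applied(self):
        t = self._toy_table()
        t.loc[0, "gm_tsc"] = 1000.0
        c = nq.compare_groups(t, "gm_tsc", exclude_ids=["s0"])
        assert c.n_p == 2
        assert c.mean_p == pytest.approx(34.5)

    def test_missing_group_metric_rejected(self):
        t = self._toy_table()
        t.loc[t.group == "control", "gm_tsc"] = np.nan
        with pytest.raises(InputError):
            nq.compare_groups(t, "gm_tsc")


def test_outcome_correlations_table_shape():
    t = nq.simulate_cohort(nq.CohortSpec(seed=21))
    out = nq.outcome_correlations(t, ["gm_tsc", "wm_tsc"], ["btact_composite"])
    assert list(out.columns) == [
        "metric", "outcome", "n", "direct_r", "direct_p", "partial_r", "partial_p"
    ]
    assert len(out) == 2
    assert (out.n == 24).all()
    # the simulated association is positive: lower TSC, worse cognition
    assert (out.direct_r > 0).all()
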