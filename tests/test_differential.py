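import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asorescue import differential as diff
from asorescue.io_formats import AbundanceTable


def _table(design, rows: dict) -> AbundanceTable:
    return AbundanceTable(pd.DataFrame(rows, index=design.sample_ids).T)


PS_VS_CS = diff.Contrast(("proband", "ASO_S"), ("control", "ASO_S"))


def bh_bruteforce(p: np.ndarray) -> np.ndarray:
    """Independent BH oracle: sort, scale by m/rank, cumulative min from the
    largest rank, cap at 1."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestLog2FC:
    def test_identity_and_arithmetic(self, four_arm_design):
        t = _table(four_arm_design,
                   {"F1": [10, 10, 0, 0, 10, 10, 0, 0],
                    "F2": [2, 4, 0, 0, 1, 1, 0, 0]})
        lfc = diff.log2_fold_change(t, four_arm_design, PS_VS_CS)
        assert lfc["F1"] == 0.0
        assert lfc["F2"] == pytest.approx(2.0)

    def test_minus_1_9_means_26_8_percent_of_reference(self):
        assert round(diff.percent_of_reference(-1.9), 1) == 26.8

    def test_empty_arm_gives_missing_not_zero(self, four_arm_design):
        values = pd.DataFrame(
            {"F1": [np.nan, np.nan, 1, 1, 2, 2, 3, 3]},
            index=four_arm_design.sample_ids,
        ).T
        t = AbundanceTable(values)
        lfc = diff.log2_fold_change(t, four_arm_design, PS_VS_CS)
        assert np.isnan(lfc["F1"])


class TestTwoSampleTest:
    def test_welch_small_arms_frozen(self):
        # direct evaluation of the Welch formulas for {1,2,3} vs {2,3,4}:
        # t = -1 / sqrt(1/3 + 1/3), df = (2/3)^2 / (2 * (1/9) / 2)
        t, df, p = diff.welch_t(np.array([[1.0, 2, 3]]), np.array([[2.0, 3, 4]]))
        assert t[0] == pytest.approx(-1.2247448714, abs=1e-9)
        assert df[0] == pytest.approx(4.0, abs=1e-12)

    def test_identical_arms(self):
        t, _, p = diff.welch_t(np.array([[1.0, 2, 3]]), np.array([[1.0, 2, 3]]))
        assert t[0] == 0.0 and p[0] == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(20, 4))
        b = rng.normal(size=(20, 5))
        t1, _, p1 = diff.welch_t(a, b)
        t2, _, p2 = diff.welch_t(b, a)
        np.testing.assert_allclose(t1, -t2, atol=1e-12)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_agrees_with_scipy_reference(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n1, n2 = rng.integers(2, 8, size=2)
            a = rng.normal(size=(1, n1))
            b = rng.normal(size=(1, n2))
            t, df, p = diff.welch_t(a, b)
            ref = stats.ttest_ind(a[0], b[0], equal_var=False)
            assert t[0] == pytest.approx(ref.statistic, abs=1e-10)
            assert df[0] == pytest.approx(ref.df, abs=1e-10)
            assert p[0] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_pooled_agrees_with_scipy(self):
        rng = np.random.default_rng(43)
        a, b = rng.normal(size=(1, 4)), rng.normal(size=(1, 6))
        t, df, p = diff.pooled_t(a, b)
        ref = stats.ttest_ind(a[0], b[0], equal_var=True)
        assert t[0] == pytest.approx(ref.statistic, abs=1e-10)
        assert df[0] == 8

    def test_zero_variance_unequal_means(self):
        t, _, p = diff.welch_t(np.array([[1.0, 1, 1]]), np.array([[2.0, 2, 2]]))
        assert np.isinf(t[0]) and 0 < p[0] < 1e-300

    def test_too_few_values_missing(self):
        t, df, p = diff.welch_t(np.array([[1.0, np.nan, np.nan]]),
                                np.array([[1.0, 2, 3]]))
        assert np.isnan(t[0]) and np.isnan(p[0])


class TestBH:
    def test_frozen_examples(self):
        np.testing.assert_allclose(
            diff.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4)
        assert diff.bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)
        np.testing.assert_allclose(diff.bh_adjust(np.ones(5)), np.ones(5))

    @pytest.mark.parametrize("n", [1, 2, 10, 333, 1000])
    def test_matches_bruteforce(self, n):
        rng = np.random.default_rng(n)
        p = rng.random(n)
        np.testing.assert_allclose(diff.bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_nan_excluded_from_family(self):
        p = np.array([0.01, np.nan, 0.02])
        q = diff.bh_adjust(p)
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_bruteforce(p[[0, 2]]), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diff.bh_adjust(np.array([0.5, 1.5]))


class TestZScores:
    def test_simple_and_constant(self, four_arm_design):
        t = _table(four_arm_design,
                   {"F1": [1, 2, 3, 1, 2, 3, 1, 2],
                    "F2": [5.0] * 8})
        z = diff.z_scores(t)
        assert z.constant_features == ["F2"]
        assert (z.values.loc["F2"] == 0).all()

    def test_three_point_feature(self):
        values = pd.DataFrame({"F1": [1.0, 2.0, 3.0]}, index=["a", "b", "c"]).T
        z = diff.z_scores(AbundanceTable(values))
        np.testing.assert_allclose(z.values.loc["F1"], [-1, 0, 1])

    def test_normalisation_property(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.normal(size=(50, 9)))
        values.columns = [f"s{i}" for i in range(9)]
        values.index = [f"f{i}" for i in range(50)]
        z = diff.z_scores(AbundanceTable(values)).values.to_numpy()
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)


class TestRunContrast:
    def test_missing_feature_excluded_from_family(self, four_arm_design):
        rows = {"F1": [1, 2, 0, 0, 1.5, 2.5, 0, 0],
                "F2": [np.nan, np.nan, 0, 0, 1, 2, 0, 0]}
        t = _table(four_arm_design, rows)
        res = diff.run_contrast(t, four_arm_design, PS_VS_CS)
        assert np.isnan(res.loc["F2", "p"]) and not res.loc["F2", "significant"]
        # family size 1: q == p for the complete feature
        assert res.loc["F1", "q"] == pytest.approx(res.loc["F1", "p"])

    def test_significance_needs_both_thresholds(self, four_arm_design):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 0.01, size=(1, 8))
        base[0, :2] += 0.19  # clear q but below the fold-change cutoff
        t = AbundanceTable(pd.DataFrame(base, index=["F1"],
                                        columns=four_arm_design.sample_ids))
        res = diff.run_contrast(t, four_arm_design, PS_VS_CS)
        assert abs(res.loc["F1", "log2FC"]) < 0.2
        assert not res.loc["F1", "significant"]

    def test_unknown_method_rejected(self, small_table, four_arm_design):
        with pytest.raises(ValueError):
            diff.two_sample_test(small_table, four_arm_design, PS_VS_CS,
                                 method="bogus")

    def test_arm_with_one_sample_rejected(self, small_table, four_arm_design):
        design = four_arm_design
        design.table.drop(index="PS2", inplace=True)
        with pytest.raises(diff.ContrastError, match="at least 2"):
            diff.run_contrast(small_table, design, PS_VS_CS)
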