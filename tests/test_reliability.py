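"""Agreement and test-retest statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import petkin as pk

WORKED = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])


class TestAnova:
    def test_worked_example(self):
        d = pk.anova_decompose(WORKED)
        assert d.ms_r == pytest.approx(8.0)
        assert d.ms_c == pytest.approx(1.5)
        assert d.ms_e == pytest.approx(0.0, abs=1e-12)

    def test_constant_matrix(self):
        d = pk.anova_decompose(np.full((4, 2), 7.0))
        assert d.ms_r == d.ms_c == d.ms_e == d.ms_w == 0.0

    def test_translation_moves_only_grand_mean(self):
        a = pk.anova_decompose(WORKED)
        b = pk.anova_decompose(WORKED + 10.0)
        assert b.grand_mean == pytest.approx(a.grand_mean + 10.0)
        for f in ("ms_r", "ms_c", "ms_e", "ms_w"):
            assert getattr(b, f) == pytest.approx(getattr(a, f))

    def test_sum_of_squares_reconstruction(self):
        rng = np.random.default_rng(3)
        m = rng.normal(5, 2, (7, 3))
        d = pk.anova_decompose(m)
        n, k = m.shape
        total = ((n - 1) * d.ms_r + (k - 1) * d.ms_c
                 + (n - 1) * (k - 1) * d.ms_e)
        assert total == pytest.approx(np.sum((m - m.mean()) ** 2))


class TestIcc:
    def test_worked_example_is_eight_ninths(self):
        assert pk.icc_a1(WORKED) == pytest.approx(8.0 / 9.0, abs=1e-12)

    def test_identical_columns_give_one(self):
        m = np.column_stack([[1.0, 4.0, 9.0], [1.0, 4.0, 9.0]])
        assert pk.icc_a1(m) == pytest.approx(1.0)

    def test_no_variance_returns_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isnan(pk.icc_a1(np.full((3, 2), 2.0)))

    def test_variance_components_simulation(self):
        # true ICC = sigma_b^2 / (sigma_b^2 + sigma_w^2) = 0.5
        rng = np.random.default_rng(12)
        subj = rng.normal(10, 1.0, 2000)
        m = subj[:, None] + rng.normal(0, 1.0, (2000, 2))
        assert pk.icc_a1(m) == pytest.approx(0.5, abs=0.05)

    def test_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = rng.integers(4, 10)
            m = rng.normal(5, 2, (n, 2)) + rng.normal(0, 1, (n, 1))
            df = pd.DataFrame({
                "targets": np.repeat(np.arange(n), 2),
                "raters": np.tile([0, 1], n),
                "scores": m.ravel(),
            })
            icc2 = pingouin.intraclass_corr(df, targets="targets",
                                            raters="raters", ratings="scores")
            oracle = icc2.set_index("Type").loc["ICC(A,1)", "ICC"]
            assert pk.icc_a1(m) == pytest.approx(oracle, abs=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_never_exceeds_one(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(0, 1, (rng.integers(2, 8), rng.integers(2, 4)))
        assert pk.icc_a1(m) <= 1.0 + 1e-12


class TestScalarMetrics:
    def test_bias(self):
        assert pk.bias_percent([1, 2, 3], [1, 2, 3]) == 0.0
        assert pk.bias_percent([105.0], [100.0]) == pytest.approx(5.0)
        assert pk.bias_percent([94.12], [100.0]) == pytest.approx(-5.88)
        with pytest.raises(pk.ValidationError):
            pk.bias_percent([1.0], [0.0])

    def test_cv(self):
        assert pk.cv_percent([90.0, 100.0, 110.0]) == pytest.approx(10.0)
        assert pk.cv_percent([5.0, 5.0, 5.0]) == 0.0
        assert pk.cv_percent(3.7 * np.array([90.0, 100.0, 110.0])) == \
            pytest.approx(10.0)

    def test_wscv_worked_example(self):
        m = np.array([[10.0, 12.0], [20.0, 18.0], [30.0, 33.0]])
        expected = np.sqrt(8.5 / 3.0) / 20.5 * 100.0  # hand ANOVA: MS_W = 8.5/3
        assert pk.wscv_percent(m) == pytest.approx(expected)
        assert pk.wscv_percent(np.array([[1.0, 1.0], [2.0, 2.0]])) == 0.0

    def test_wscv_simulation(self):
        rng = np.random.default_rng(21)
        subj = rng.normal(10.0, 0.5, 2000)
        m = subj[:, None] + rng.normal(0, 1.0, (2000, 2))
        assert pk.wscv_percent(m) == pytest.approx(10.0, abs=1.0)

    def test_av(self):
        av, mean = pk.av_percent([10.0], [10.0])
        assert mean == 0.0
        av, mean = pk.av_percent([9.0], [11.0])
        assert mean == pytest.approx(20.0)
        a1, m1 = pk.av_percent([9.0, 5.0], [11.0, 6.0])
        a2, m2 = pk.av_percent([11.0, 6.0], [9.0, 5.0])
        assert np.allclose(a1, a2) and m1 == m2

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.1, 100.0))
    def test_scale_invariance(self, c):
        m = np.array([[10.0, 12.0], [20.0, 18.0], [30.0, 33.0]])
        assert pk.wscv_percent(c * m) == pytest.approx(pk.wscv_percent(m))
        assert pk.cv_percent(c * m.ravel()) == pytest.approx(pk.cv_percent(m.ravel()))
        av1, _ = pk.av_percent(m[:, 0], m[:, 1])
        av2, _ = pk.av_percent(c * m[:, 0], c * m[:, 1])
        assert np.allclose(av1, av2)
        assert pk.bias_percent(c * m[:, 0], c * m[:, 1]) == \
            pytest.approx(pk.bias_percent(m[:, 0], m[:, 1]))


def _long(values, model="srtm", region="target"):
    rows = []
    for i, (v1, v2) in enumerate(values):
        rows.append({"subject": i + 1, "session": 1, "region": region,
                     "model": model, "estimate": v1})
        rows.append({"subject": i + 1, "session": 2, "region": region,
                     "model": model, "estimate": v2})
    return pd.DataFrame(rows)


class TestAgreementReport:
    def test_identical_tools(self):
        a = _long([(1.0, 1.1), (2.0, 2.2), (3.0, 2.9), (4.0, 4.2)])
        rep = pk.agreement_report(a, a.copy())
        assert rep["pearson_r"].iloc[0] == pytest.approx(1.0)
        assert rep["icc"].iloc[0] == pytest.approx(1.0)
        assert rep["bias_percent"].iloc[0] == 0.0

    def test_proportional_shift_penalises_icc_not_r(self):
        a = _long([(1.0, 1.1), (2.0, 2.2), (3.0, 2.9), (4.0, 4.2), (5.0, 5.1)])
        b = a.copy()
        b["estimate"] = 1.10 * b["estimate"]
        rep = pk.agreement_report(a, b)
        assert rep["pearson_r"].iloc[0] == pytest.approx(1.0)
        assert rep["bias_percent"].iloc[0] == pytest.approx(100 * (1 / 1.1 - 1))
        assert rep["icc"].iloc[0] < 1.0

    def test_pearson_matches_textbook_formula(self):
        rng = np.random.default_rng(9)
        a = _long([(v, v + 1) for v in rng.normal(3, 1, 8)])
        b = a.copy()
        b["estimate"] = b["estimate"] + rng.normal(0, 0.2, len(b))
        rep = pk.agreement_report(a, b)
        x = a["estimate"].to_numpy()
        y = b["estimate"].to_numpy()
        xc, yc = x - x.mean(), y - y.mean()
        r_oracle = np.sum(xc * yc) / np.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2))
        assert rep["pearson_r"].iloc[0] == pytest.approx(r_oracle, abs=1e-12)

    def test_unmatched_keys_listed(self):
        a = _long([(1.0, 1.1), (2.0, 2.2), (3.0, 3.3)])
        b = a[a["subject"] != 3]
        with pytest.raises(pk.ValidationError, match="unmatched"):
            pk.agreement_report(a, b)


class TestTrtReport:
    def test_retest_identical_to_test(self):
        t = _long([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)])
        test, retest = t[t.session == 1], t[t.session == 2]
        rep = pk.trt_report(test, retest)
        assert rep["icc"].iloc[0] == pytest.approx(1.0)
        assert rep["wscv_percent"].iloc[0] == 0.0
        assert rep["av_percent"].iloc[0] == 0.0

    def test_recovers_variance_components(self):
        rng = np.random.default_rng(31)
        subj = rng.normal(3.0, 0.5, 500)
        vals = [(s + rng.normal(0, 0.5), s + rng.normal(0, 0.5)) for s in subj]
        t = _long(vals)
        rep = pk.trt_report(t[t.session == 1], t[t.session == 2])
        assert rep["icc"].iloc[0] == pytest.approx(0.5, abs=0.08)

    def test_av_approximates_scaled_wscv(self):
        # for small noise, E[AV] -> (2/sqrt(pi)) * WSCV (half-normal mean)
        rng = np.random.default_rng(8)
        subj = rng.normal(100.0, 5.0, 4000)
        vals = [(s + rng.normal(0, 1.0), s + rng.normal(0, 1.0)) for s in subj]
        t = _long(vals)
        rep = pk.trt_report(t[t.session == 1], t[t.session == 2])
        ratio = rep["av_percent"].iloc[0] / rep["wscv_percent"].iloc[0]
        assert ratio == pytest.approx(2.0 / np.sqrt(np.pi), rel=0.05)

    def test_incomplete_subject_excluded_with_warning(self):
        t = _long([(1.0, 1.2), (2.0, 2.1), (3.0, 3.3)])
        test, retest = t[t.session == 1], t[t.session == 2]
        retest = retest[retest["subject"] != 2]
        with pytest.warns(UserWarning, match="missing a"):
            rep = pk.trt_report(test, retest)
        assert rep["n"].iloc[0] == 2


class TestFlagOutliers:
    @staticmethod
    def _table(values):
        rows = []
        for i, (v1, v2) in enumerate(values):
            rows.append({"subject": i + 1, "session": 1, "value": v1})
            rows.append({"subject": i + 1, "session": 2, "value": v2})
        return pd.DataFrame(rows)

    def test_homogeneous_cohort_unflagged(self):
        t = self._table([(1.0, 1.1), (1.2, 1.0), (0.9, 1.1), (1.0, 0.95)])
        assert not pk.flag_outliers(t)["flag"].any()

    def test_gross_inflation_flagged(self):
        t = self._table([(1.0, 1.1), (1.2, 1.0), (0.9, 1.1), (1.0, 50.0)])
        flags = pk.flag_outliers(t)
        flagged = flags[flags["flag"]]
        assert len(flagged) == 1
        assert flagged.iloc[0]["subject"] == 4
        assert flagged.iloc[0]["value"] == 50.0

    def test_value_below_z_threshold_not_flagged(self):
        base = [(1.0, 1.1), (1.2, 1.0), (0.9, 1.1), (1.0, 0.95), (1.1, 1.05)]
        t = self._table(base)
        vals = t["value"].to_numpy().copy()
        # place the last value at 4.9 leave-one-out SDs (below the 5-SD rule)
        rest = vals[:-2]  # other subjects' measurements
        target = rest.mean() + 4.9 * rest.std(ddof=1)
        t.loc[t.index[-1], "value"] = target
        flags = pk.flag_outliers(t, combine="or")
        assert not flags["flag"].iloc[-1]

    def test_both_criteria_required_by_default(self):
        # extreme z-score but < 500% within-subject change: unflagged by AND
        t = self._table([(1.0, 1.1), (1.2, 1.0), (0.9, 1.1), (9.0, 8.0)])
        assert not pk.flag_outliers(t)["flag"].any()
        # OR combination flags it
        assert pk.flag_outliers(t, combine="or")["flag"].any()

    def test_needs_three_subjects(self):
        t = self._table([(1.0, 1.1), (1.2, 1.0)])
        with pytest.raises(pk.ValidationError):
            pk.flag_outliers(t)
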