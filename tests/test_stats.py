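"""Correlation statistics against frozen high-precision oracles and invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from psrquant import (
    compare_dependent_correlations,
    correlation_report,
    fisher_z,
    linreg_r2,
    spearman,
)


class TestSpearman:
    def test_monotone_is_one(self):
        assert spearman([1, 2, 3], [10, 20, 30]).r == pytest.approx(1.0)

    def test_antimonotone_is_minus_one(self):
        assert spearman([1, 2, 3], [30, 20, 10]).r == pytest.approx(-1.0)

    def test_tied_example_matches_rank_pearson_oracle(self):
        """Oracle: Pearson on mean ranks (1, 2.5, 2.5, 4) vs (1, 3, 2, 4)."""
        res = spearman([1, 2, 2, 4], [1, 3, 2, 4])
        rx = np.array([1.0, 2.5, 2.5, 4.0])
        ry = np.array([1.0, 3.0, 2.0, 4.0])
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.r == pytest.approx(oracle, abs=1e-12)
        assert res.r == pytest.approx(0.9487, abs=5e-5)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_missing_values_removed_pairwise(self):
        res = spearman([1, 2, np.nan, 4, 5], [2, 4, 1, np.nan, 10])
        assert res.n == 3 and res.r == pytest.approx(1.0)

    @given(st.permutations(list(range(8))))
    def test_invariant_under_monotone_transform(self, perm):
        x = np.array(perm, float)
        y = np.arange(8.0)
        base = spearman(x, y).r
        assert spearman(np.exp(x), y).r == pytest.approx(base)
        assert spearman(x, 3 * y + 2).r == pytest.approx(base)


class TestFisherZ:
    def test_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_096_frozen_value(self):
        assert fisher_z(0.96) == pytest.approx(1.94591014906, abs=1e-9)  # 0.5*ln(49)

    def test_domain(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)

    @given(st.floats(-0.999, 0.999))
    def test_antisymmetry_and_tanh_roundtrip(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)
        assert np.tanh(fisher_z(r)) == pytest.approx(r, abs=1e-12)

    def test_strictly_increasing(self):
        rs = np.linspace(-0.99, 0.99, 50)
        zs = [fisher_z(r) for r in rs]
        assert np.all(np.diff(zs) > 0)


class TestDependentComparison:
    def test_equal_correlations_give_null(self):
        res = compare_dependent_correlations(0.7, 0.7, 0.5, 35)
        assert res.z_stat == 0.0
        assert res.p_one_sided == pytest.approx(0.5)

    def test_frozen_example(self):
        """Steiger Z on r12=0.96, r13=0.81, r23=0.8266, n=35 (exact-arithmetic oracle)."""
        res = compare_dependent_correlations(0.96, 0.81, 0.8266, 35)
        assert res.z_stat == pytest.approx(4.419394709, abs=1e-6)
        assert res.p_one_sided < 1e-4

    def test_monotone_in_r12(self):
        zs = [compare_dependent_correlations(r, 0.6, 0.5, 30).z_stat
              for r in np.linspace(0.6, 0.95, 15)]
        assert np.all(np.diff(zs) > 0)

    def test_independent_variant(self):
        res = compare_dependent_correlations(0.96, 0.81, 0.8266, 35,
                                             variant="fisher_independent")
        oracle = (np.arctanh(0.96) - np.arctanh(0.81)) / np.sqrt(2 / 32)
        assert res.z_stat == pytest.approx(oracle, abs=1e-12)

    def test_small_n_and_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            compare_dependent_correlations(0.5, 0.4, 0.3, 3)
        with pytest.raises(ValueError):
            compare_dependent_correlations(1.0, 0.4, 0.3, 30)

    def test_alternatives(self):
        g = compare_dependent_correlations(0.9, 0.5, 0.4, 30, alternative="greater")
        l = compare_dependent_correlations(0.9, 0.5, 0.4, 30, alternative="less")
        t = compare_dependent_correlations(0.9, 0.5, 0.4, 30, alternative="two_sided")
        assert g.p_one_sided + l.p_one_sided == pytest.approx(1.0)
        assert t.p_one_sided == pytest.approx(2 * g.p_one_sided)


class TestRegression:
    def test_exact_line(self):
        res = linreg_r2([0, 1, 2, 3], [0, 2, 4, 6])
        assert (res.slope, res.intercept, res.r_squared) == pytest.approx((2.0, 0.0, 1.0))

    def test_closed_form_example(self):
        res = linreg_r2([0, 1, 2], [0, 1, 1])
        assert res.slope == pytest.approx(0.5)
        assert res.intercept == pytest.approx(1 / 6)
        assert res.r_squared == pytest.approx(0.75)

    def test_constant_y_has_zero_r2(self):
        assert linreg_r2([0, 1, 2], [5, 5, 5]).r_squared == pytest.approx(0.0)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linreg_r2([1, 1, 1], [1, 2, 3])

    def test_r2_scale_shift_invariant(self):
        x = np.array([0.0, 1, 2, 4, 7])
        y = np.array([1.0, 2, 2, 5, 9])
        base = linreg_r2(x, y).r_squared
        assert linreg_r2(10 * x - 3, 0.5 * y + 4).r_squared == pytest.approx(base)


class TestReport:
    @staticmethod
    def _cohort(n=8, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        cpa = np.linspace(0.5, 12.0, n)
        hyp = 25 * cpa + 150 + rng.normal(0, noise, n)
        stage = np.digitize(cpa, [1, 2, 4, 8, 14, 22]).astype(str)
        return pd.DataFrame({"mean_cpa": cpa, "hyp_ug_per_g": hyp, "ishak": stage})

    def test_noiseless_hyp_correlates_perfectly(self):
        rep = correlation_report(self._cohort(noise=0.0))
        assert rep["cpa_vs_hyp"].r == pytest.approx(1.0)

    def test_schema(self):
        rep = correlation_report(self._cohort(noise=30.0))
        assert list(rep["per_system"].columns) == ["system", "r_CPA", "r_HYP",
                                                   "r23", "n", "Z", "p_one_sided"]
        assert rep["regression_20x_40x"] is None

    def test_cpa_correlates_at_least_as_well_as_noisy_hyp(self):
        """Stages derive from CPA, so the noisy HYP arm cannot beat the CPA arm."""
        rep = correlation_report(self._cohort(n=24, noise=60.0, seed=3))
        row = rep["per_system"].iloc[0]
        assert row["r_CPA"] >= row["r_HYP"]
        assert row["Z"] >= 0

    def test_regression_included_when_both_resolutions_present(self):
        df = self._cohort()
        df["cpa_40x"] = df["mean_cpa"]
        df["cpa_20x"] = df["mean_cpa"] * 1.01
        rep = correlation_report(df)
        assert rep["regression_20x_40x"].r_squared == pytest.approx(1.0)

    def test_fewer_than_four_animals_rejected(self):
        with pytest.raises(ValueError):
            correlation_report(self._cohort(n=3))


def test_type_one_error_calibration_montecarlo():
    """Steiger test attains ~5% rejections under a trivariate-normal null.

    20 000 samples of n=35 with rho12 = rho13 = 0.7, rho23 = 0.5; sample
    correlations per draw; reject when the one-sided p < 0.05.
    """
    reps, n = 20_000, 35
    cov = np.array([[1.0, 0.7, 0.7], [0.7, 1.0, 0.5], [0.7, 0.5, 1.0]])
    rng = np.random.default_rng(2026)
    data = rng.multivariate_normal(np.zeros(3), cov, size=(reps, n))
    data -= data.mean(axis=1, keepdims=True)
    data /= np.linalg.norm(data, axis=1, keepdims=True)
    r12 = np.einsum("ij,ij->i", data[:, :, 0], data[:, :, 1])
    r13 = np.einsum("ij,ij->i", data[:, :, 0], data[:, :, 2])
    r23 = np.einsum("ij,ij->i", data[:, :, 1], data[:, :, 2])
    rejections = sum(
        compare_dependent_correlations(a, b, c, n).p_one_sided < 0.05
        for a, b, c in zip(r12, r13, r23)
    )
    rate = rejections / reps
    assert 0.04 <= rate <= 0.06
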