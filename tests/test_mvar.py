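import numpy as np
import pytest

from cpgc import (
    MVAR,
    SubjectTimeSeries,
    fit_model,
    pearson_matrix,
    select_order_bic,
)
from cpgc.benchmarks import ols_oracle_max_error, purging_trial
from cpgc.mvar import min_timepoints


class TestFitModel:
    def test_white_noise_coefficients_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5000, 2))
        m = fit_model(x, order=1, include_zero_lag=True)
        assert np.max(np.abs(m.zero_lag_)) < 0.05
        assert np.max(np.abs(m.lag_coeffs_[0])) < 0.05

    def test_recovers_planted_lag_coefficient(self):
        rng = np.random.default_rng(1)
        t = 5000
        x1 = rng.normal(size=t)
        x2 = np.zeros(t)
        x2[1:] = 0.5 * x1[:-1] + rng.normal(size=t - 1)
        m = fit_model(np.column_stack([x1, x2]), order=1)
        assert abs(m.lag_coeffs_[0][1, 0] - 0.5) < 0.05
        # all other lag entries are noise around zero
        other = m.lag_coeffs_[0].copy()
        other[1, 0] = 0.0
        assert np.max(np.abs(other)) < 0.05

    def test_zero_lag_diagonal_is_exactly_zero(self, rng):
        m = fit_model(rng.normal(size=(300, 4)), order=2)
        assert np.all(np.diag(m.zero_lag_) == 0.0)

    def test_duplicate_columns_raise_named_error(self, rng):
        x = rng.normal(size=(200, 2))
        data = np.column_stack([x[:, 0], x[:, 0], x[:, 1]])
        ts = SubjectTimeSeries(data=data, region_names=["u", "v", "w"])
        with pytest.raises(np.linalg.LinAlgError, match="u~v"):
            fit_model(ts, order=1)

    def test_too_short_series_reports_minimum(self, rng):
        with pytest.raises(ValueError, match=str(min_timepoints(9, 1))):
            fit_model(rng.normal(size=(12, 9)), order=1)

    def test_residuals_orthogonal_to_regressors(self, rng):
        x = rng.normal(size=(400, 3))
        m = fit_model(x, order=2, include_zero_lag=True)
        p = 2
        lagged = np.column_stack([x[p - n : -n, :] for n in range(1, p + 1)])
        for i in range(3):
            others = [j for j in range(3) if j != i]
            regressors = np.column_stack([x[p:, others], lagged])
            dots = np.abs(regressors.T @ m.residuals_[:, i])
            bounds = 1e-6 * np.linalg.norm(regressors, axis=0) * np.linalg.norm(m.residuals_[:, i])
            assert np.all(dots < bounds)

    def test_matches_normal_equations_oracle(self):
        assert ols_oracle_max_error(seed=0, k=3, p=2, T=50) < 1e-8


class TestOrderSelection:
    def test_white_noise_selects_order_one(self, rng):
        x = rng.normal(size=(500, 3))
        assert select_order_bic(x, p_max=4) == 1

    def test_precondition_violation_raises(self, rng):
        with pytest.raises(ValueError, match="too short"):
            select_order_bic(rng.normal(size=(25, 3)), p_max=5)

    def test_selected_order_is_argmin_of_reported_bic(self, rng):
        x = rng.normal(size=(400, 3))
        m = MVAR(order="bic", p_max=4).fit(x)
        assert m.order_ == min(m.bic_values_, key=lambda p: (m.bic_values_[p], p))


class TestCausalityMatrix:
    def _manual_model(self, lags):
        m = MVAR(order=len(lags))
        m.lag_coeffs_ = [np.asarray(a, dtype=float) for a in lags]
        m.zero_lag_ = np.zeros_like(m.lag_coeffs_[0])
        m.include_zero_lag = True
        return m

    def test_single_coefficient_read_off(self):
        a = np.zeros((3, 3))
        a[1, 0] = 0.5
        m = self._manual_model([a])
        expected = np.zeros((3, 3))
        expected[1, 0] = 0.5
        assert np.array_equal(m.causality_matrix(), expected)

    def test_lag_summation_and_absolute_flag(self):
        a1 = np.zeros((2, 2))
        a2 = np.zeros((2, 2))
        a1[1, 0] = 0.3
        a2[1, 0] = 0.2
        m = self._manual_model([a1, a2])
        assert m.causality_matrix()[1, 0] == pytest.approx(0.5)
        a2[1, 0] = -0.2
        assert m.causality_matrix()[1, 0] == pytest.approx(0.1)
        assert m.causality_matrix(absolute=True)[1, 0] == pytest.approx(0.5)

    def test_unfitted_model_raises(self):
        with pytest.raises(ValueError, match="not fitted"):
            MVAR(order=1).causality_matrix()

    def test_purging_of_instantaneous_copy(self):
        naive, purged = purging_trial(seed=3)
        assert naive > 5 * purged
        assert purged < 0.05

    @pytest.mark.parametrize("seed", range(5))
    def test_diagonals_zero_on_random_fits(self, seed):
        rng = np.random.default_rng(seed)
        m = fit_model(rng.normal(size=(250, 4)), order=1)
        assert np.all(np.diag(m.causality_matrix()) == 0.0)
        assert np.all(np.diag(m.instantaneous_matrix()) == 0.0)


class TestInstantaneousMatrix:
    def test_shared_innovation_recovered(self):
        rng = np.random.default_rng(7)
        t = 5000
        cov = np.array([[1.0, 0.8], [0.8, 1.0]])
        e = rng.multivariate_normal([0, 0], cov, size=t)
        x = (e - e.mean(0)) / e.std(0, ddof=1)
        inst = fit_model(x, order=1).instantaneous_matrix()
        assert inst[0, 1] == pytest.approx(0.8, abs=0.07)
        assert inst[0, 1] == inst[1, 0]

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(8)
        inst = fit_model(rng.normal(size=(5000, 3)), order=1).instantaneous_matrix()
        assert np.max(np.abs(inst)) < 0.05

    def test_plain_var_has_no_instantaneous(self, rng):
        m = fit_model(rng.normal(size=(300, 3)), order=1, include_zero_lag=False)
        with pytest.raises(ValueError, match="zero-lag"):
            m.instantaneous_matrix()


class TestPearsonMatrix:
    def test_unit_diagonal_and_symmetry(self, rng):
        r = pearson_matrix(rng.normal(size=(500, 4)))
        assert np.array_equal(np.diag(r), np.ones(4))
        assert np.array_equal(r, r.T)

    def test_orthogonal_sinusoids(self):
        t = np.arange(1000)
        x = np.column_stack([np.sin(2 * np.pi * t / 100), np.cos(2 * np.pi * t / 100)])
        r = pearson_matrix(x)
        assert abs(r[0, 1]) < 0.01

    def test_recovers_population_correlation(self):
        rng = np.random.default_rng(9)
        cov = np.array([[1.0, 0.6], [0.6, 1.0]])
        x = rng.multivariate_normal([0, 0], cov, size=5000)
        assert pearson_matrix(x)[0, 1] == pytest.approx(0.6, abs=0.05)

    def test_zero_variance_rejected(self):
        x = np.column_stack([np.ones(100), np.arange(100.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_matrix(x)
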