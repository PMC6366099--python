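"""Marginal likelihood, ML fitting and posterior prediction of the hierarchy."""

import numpy as np
import pytest

from lipidrhythm import (
    AnalyteSeries,
    HierarchicalGPRhythmModel,
    KernelParams,
    SimulationConfig,
    build_joint_covariance,
    fit_ml,
    log_marginal_likelihood,
    normalize,
    posterior_shared_curve,
    simulate_dataset,
    stack_series,
)
from lipidrhythm.gp import ModelFit, fit_model_pair


def _series(t, subj, y):
    t = np.asarray(t, float)
    return AnalyteSeries(
        analyte="L", group="g", t=t, y=np.asarray(y, float),
        subject_idx=np.asarray(subj, int), subjects=sorted(set(subj)),
    )


def _random_series(rng, n):
    return _series(
        rng.uniform(0, 48, n), rng.integers(0, max(1, n // 4), n), rng.normal(size=n)
    )


class TestLogMarginalLikelihood:
    def test_single_point_standard_normal(self):
        """n=1, y=0, unit noise variance: -log(2 pi)/2."""
        s = _series([0.0], [0], [0.0])
        p = KernelParams(sigma2_p=0.0, sigma2_m=0.0, sigma2_n=1.0)
        lml = log_marginal_likelihood(s, p, include_shared=False, jitter=0.0)
        assert lml == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    @pytest.mark.parametrize("y1,v", [(0.7, 1.0), (-1.2, 0.3), (2.0, 4.0)])
    def test_single_point_closed_form(self, y1, v):
        s = _series([3.0], [0], [y1])
        p = KernelParams(sigma2_p=0.0, sigma2_m=0.0, sigma2_n=v)
        lml = log_marginal_likelihood(s, p, include_shared=False, jitter=0.0)
        assert lml == pytest.approx(-0.5 * np.log(2 * np.pi * v) - y1**2 / (2 * v), abs=1e-10)

    def test_matches_dense_inverse_determinant_oracle(self):
        """Cholesky route equals explicit inverse/slogdet on random instances."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(5, 41)
            s = _random_series(rng, n)
            p = KernelParams(
                sigma2_p=rng.uniform(0.05, 2), ell_p=rng.uniform(0.2, 3),
                sigma2_m=rng.uniform(0.05, 2), ell_m=rng.uniform(1, 30),
                sigma2_n=rng.uniform(0.05, 2),
            )
            K = build_joint_covariance(s, p, include_shared=True, jitter=1e-8)
            _, logdet = np.linalg.slogdet(K)
            direct = (
                -0.5 * s.y @ np.linalg.inv(K) @ s.y
                - 0.5 * logdet
                - 0.5 * n * np.log(2 * np.pi)
            )
            assert log_marginal_likelihood(s, p) == pytest.approx(direct, abs=1e-6)

    def test_invariant_to_stacking_order(self):
        rng = np.random.default_rng(5)
        s = _random_series(rng, 24)
        p = KernelParams(sigma2_p=1.0, ell_p=1.0, sigma2_m=0.5, ell_m=8.0, sigma2_n=0.8)
        perm = rng.permutation(24)
        s_perm = _series(s.t[perm], s.subject_idx[perm], s.y[perm])
        assert log_marginal_likelihood(s, p) == pytest.approx(
            log_marginal_likelihood(s_perm, p), abs=1e-9
        )


class TestFitML:
    def test_noise_variance_recovered_on_iid_data(self):
        """sigma2_p = sigma2_m = 0, sigma2_n = 1, n = 200 stacked points."""
        rng = np.random.default_rng(11)
        s = _series(
            np.tile(np.array([18.0, 24.0, 30.0, 36.0, 42.0]), 40),
            np.repeat(np.arange(40), 5),
            rng.standard_normal(200),
        )
        fit = fit_ml(s, "null")
        assert fit.converged
        assert 0.8 <= fit.params.sigma2_n + fit.params.sigma2_m <= 1.2
        assert fit.params.sigma2_n >= 0.5  # noise dominates

    def test_constant_zero_input_pins_variances_at_bounds(self):
        s = _series([18.0, 24.0, 30.0, 36.0], [0, 0, 0, 0], [0.0, 0.0, 0.0, 0.0])
        fit = fit_ml(s, "null")
        assert fit.converged
        assert fit.params.sigma2_n == pytest.approx(1e-6, rel=1e-3)

    def test_rhythmic_variance_detected_on_strong_cosine(self):
        cfg = SimulationConfig(
            n_subjects_per_group=20, n_analytes=1, amplitude=1.0, acrophases=8.0,
            fraction_rhythmic_per_group=(1.0, 1.0), missing_rate=0.0, seed=3,
        )
        table = normalize(simulate_dataset(cfg).table)
        s = stack_series(table, table["analyte"].iloc[0], "healthy")
        fit = fit_ml(s, "rhythmic")
        assert fit.converged
        assert fit.params.sigma2_p > 0.1

    def test_warm_start_keeps_lr_nonnegative(self):
        """Rhythmic fit never falls below the null fit it nests."""
        rng = np.random.default_rng(21)
        for _ in range(5):
            s = _random_series(rng, 30)
            null, rhyt = fit_model_pair(s)
            assert rhyt.log_marginal_likelihood >= null.log_marginal_likelihood - 1e-6

    def test_subject_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        t = np.tile([18.0, 24.0, 30.0, 36.0, 42.0], 4)
        subj = np.repeat(np.arange(4), 5)
        y = rng.normal(size=20)
        relabel = np.array([2, 0, 3, 1])
        fit_a = fit_ml(_series(t, subj, y), "null")
        fit_b = fit_ml(_series(t, relabel[subj], y), "null")
        assert fit_a.log_marginal_likelihood == pytest.approx(
            fit_b.log_marginal_likelihood, abs=1e-6
        )

    def test_rejects_unknown_model_kind_and_short_series(self):
        s = _series([0.0, 6.0, 12.0], [0, 0, 0], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="model_kind"):
            fit_ml(s, "cosinor")
        short = _series([0.0, 6.0], [0, 0], [0.1, 0.2])
        with pytest.raises(ValueError, match="3 distinct"):
            fit_ml(short, "null")

    def test_estimated_periodic_variance_increases_with_amplitude(self):
        medians = []
        for amp in (0.5, 2.0):
            vals = []
            for rep in range(15):
                cfg = SimulationConfig(
                    n_subjects_per_group=10, n_analytes=1, amplitude=amp,
                    fraction_rhythmic_per_group=(1.0, 1.0), missing_rate=0.0,
                    seed=40_000 + rep,
                )
                table = normalize(simulate_dataset(cfg).table)
                s = stack_series(table, table["analyte"].iloc[0], "healthy")
                vals.append(fit_ml(s, "rhythmic").params.sigma2_p)
            medians.append(np.median(vals))
        assert medians[1] > medians[0]


class TestPosteriorCurve:
    def _fit(self, **kw):
        return ModelFit(
            params=KernelParams(**kw), log_marginal_likelihood=0.0,
            model_kind="rhythmic", converged=True, n_restarts_used=0,
        )

    def test_vanishing_shared_variance_gives_flat_zero_curve(self):
        s = _series([0.0, 6.0, 12.0], [0, 0, 0], [1.0, -1.0, 1.0])
        fit = self._fit(sigma2_p=1e-12, ell_p=1.0, sigma2_m=0.5, ell_m=6.0, sigma2_n=1.0)
        curve = posterior_shared_curve(s, fit)
        assert np.max(np.abs(curve.mean)) < 1e-9
        assert np.max(curve.sd) < 1e-5

    def test_interpolation_limit_near_noise_free_data(self):
        """Pure shared cosine, one subject, tiny noise: mean hits the data."""
        t = np.array([0.0, 4.0, 8.0, 12.0, 16.0, 20.0])
        y = np.cos(2 * np.pi * t / 24.0)
        s = _series(t, np.zeros(6, int), y)
        fit = self._fit(sigma2_p=1.0, ell_p=1.0, sigma2_m=1e-10, ell_m=6.0, sigma2_n=1e-6)
        curve = posterior_shared_curve(s, fit)
        for ti, yi in zip(t, y):
            idx = int(np.argmin(np.abs(curve.grid_t - ti)))
            assert abs(curve.mean[idx] - yi) < 0.01

    def test_reverts_to_prior_far_from_data_in_kernel_distance(self):
        """With a short periodic lengthscale, a 12 h offset is 'far'."""
        t = np.array([0.0, 24.0, 1.0, 25.0])
        y = np.array([1.0, 1.0, 0.5, 0.5])
        s = _series(t, np.zeros(4, int), y)
        fit = self._fit(sigma2_p=2.0, ell_p=0.05, sigma2_m=1e-10, ell_m=6.0, sigma2_n=0.1)
        curve = posterior_shared_curve(s, fit)
        idx = int(np.argmin(np.abs(curve.grid_t - 12.0)))
        assert curve.sd[idx] == pytest.approx(np.sqrt(2.0), rel=1e-3)
        assert abs(curve.mean[idx]) < 1e-6

    def test_variance_bounded_by_prior_and_periodic_grid(self):
        rng = np.random.default_rng(2)
        s = _random_series(rng, 20)
        fit = self._fit(sigma2_p=1.5, ell_p=1.0, sigma2_m=0.3, ell_m=8.0, sigma2_n=0.5)
        curve = posterior_shared_curve(s, fit)
        assert np.all(curve.sd >= 0)
        assert np.all(curve.sd**2 <= 1.5 + 1e-9)
        assert curve.grid_t[0] == 0.0 and curve.grid_t[-1] < 24.0

    def test_null_fit_rejected(self):
        s = _series([0.0, 6.0, 12.0], [0, 0, 0], [0.0, 0.0, 0.0])
        null = ModelFit(params=KernelParams(), log_marginal_likelihood=0.0,
                        model_kind="null", converged=True, n_restarts_used=0)
        with pytest.raises(ValueError, match="rhythmic"):
            posterior_shared_curve(s, null)


class TestEstimatorAPI:
    def test_get_set_params_round_trip(self):
        est = HierarchicalGPRhythmModel(rhythmic=False, n_restarts=3)
        params = est.get_params()
        assert params["rhythmic"] is False
        est2 = HierarchicalGPRhythmModel().set_params(**params)
        assert est2.get_params() == params

    def test_fit_predict_surface(self):
        rng = np.random.default_rng(8)
        t = np.tile([18.0, 24.0, 30.0, 36.0, 42.0], 6)
        subj = np.repeat(np.arange(6), 5)
        y = np.cos(2 * np.pi * t / 24.0) + 0.3 * rng.standard_normal(30)
        X = np.column_stack([t, subj])
        est = HierarchicalGPRhythmModel(rhythmic=True).fit(X, y)
        assert est.converged_ and np.isfinite(est.log_marginal_likelihood_)
        mu, sd = est.predict(np.arange(0, 24, 0.5), return_std=True)
        assert mu.shape == sd.shape == (48,)
        assert np.all(sd >= 0)
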