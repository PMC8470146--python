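"""Subject-level inversion: priors, conjugate oracle, step control."""
import numpy as np
import pytest

from motordcm.gaussian import GaussianDensity
from motordcm.inversion import (DCMForward, DCMInverter, compare_evidence,
                                default_priors, explained_variance)
from motordcm.vl import InversionSettings, variational_laplace_engine


class TestDefaultPriors:
    def test_m1_switches_on_left_driving_inputs(self):
        priors = default_priors("m1")
        var = dict(zip(priors.names, priors.variances))
        for cond in ("AV", "A", "V"):
            assert var[f"C_lSMA_{cond}"] > 0 and var[f"C_lPMd_{cond}"] > 0
            assert var[f"C_rSMA_{cond}"] == 0 and var[f"C_rPMd_{cond}"] == 0
            assert var[f"C_lM1_{cond}"] == 0 and var[f"C_rM1_{cond}"] == 0

    def test_m2_switches_on_right_driving_inputs(self):
        priors = default_priors("m2")
        var = dict(zip(priors.names, priors.variances))
        for cond in ("AV", "A", "V"):
            assert var[f"C_rSMA_{cond}"] > 0 and var[f"C_rPMd_{cond}"] > 0
            assert var[f"C_lSMA_{cond}"] == 0 and var[f"C_lPMd_{cond}"] == 0

    def test_all_connections_on_with_zero_mean(self):
        priors = default_priors("m1")
        var = dict(zip(priors.names, priors.variances))
        assert all(v > 0 for n, v in var.items() if n.startswith("A_"))
        assert np.all(priors.mean == 0.0)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            default_priors("m3")


class TestConjugateOracle:
    """With a linear forward model and fixed noise the posterior has a
    closed conjugate form; the iterative scheme must reproduce it."""

    def setup_method(self):
        rng = np.random.default_rng(0)
        self.n, self.p = 40, 3
        self.X = rng.normal(size=(self.n, self.p))
        self.sigma2 = 0.25
        beta = np.array([0.5, -1.0, 0.2])
        self.y = self.X @ beta + rng.normal(scale=0.5, size=self.n)
        self.prior = GaussianDensity.diagonal(
            ["b0", "b1", "b2"], np.zeros(3), np.full(3, 2.0))
        self.settings = InversionSettings(
            fixed_noise_log_precision=np.log(1 / self.sigma2),
            convergence_tolerance=1e-10, max_iterations=200)

    def _closed_form(self):
        P = self.X.T @ self.X / self.sigma2 + np.eye(self.p) / 2.0
        S = np.linalg.inv(P)
        return S @ (self.X.T @ self.y / self.sigma2), S

    def test_posterior_matches_closed_form(self):
        post = variational_laplace_engine(
            lambda th: self.X @ th, self.y, self.prior, settings=self.settings)
        mu, S = self._closed_form()
        assert np.abs(post.mean - mu).max() / np.abs(mu).max() < 1e-6
        assert np.abs(post.cov - S).max() / np.abs(S).max() < 1e-6

    def test_free_energy_matches_exact_evidence(self):
        from scipy.stats import multivariate_normal

        post = variational_laplace_engine(
            lambda th: self.X @ th, self.y, self.prior, settings=self.settings)
        Cy = self.X @ (2.0 * np.eye(self.p)) @ self.X.T \
            + self.sigma2 * np.eye(self.n)
        exact = multivariate_normal(np.zeros(self.n), Cy).logpdf(self.y)
        assert post.free_energy == pytest.approx(exact, abs=1e-6)

    def test_trajectory_monotone(self):
        post = variational_laplace_engine(
            lambda th: self.X @ th, self.y, self.prior, settings=self.settings)
        assert np.all(np.diff(post.meta["trajectory"]) >= 0)


class TestDCMInversion:
    @pytest.fixture(scope="class")
    def quick_fit(self, small_inputs, neg_template):
        from motordcm.cohort import NoiseSpec, simulate_subject_timeseries

        y = simulate_subject_timeseries(neg_template, small_inputs,
                                        NoiseSpec("white", 1.0), seed=2)
        inv = DCMInverter(variant="m1",
                          settings=InversionSettings(max_iterations=8))
        return inv.fit(small_inputs, y), y

    def test_free_energy_monotone_over_accepted_steps(self, quick_fit):
        inv, _ = quick_fit
        assert np.all(np.diff(inv.posterior_.meta["trajectory"]) >= 0)

    def test_switched_off_parameters_identical_to_prior(self, quick_fit):
        inv, _ = quick_fit
        priors = default_priors("m1")
        for i, (name, v) in enumerate(zip(priors.names, priors.variances)):
            if v == 0.0:
                assert inv.posterior_.mean[i] == priors.mean[i]
                assert not inv.posterior_.cov[i].any()

    def test_posterior_carries_noise_hyperparameters(self, quick_fit):
        inv, _ = quick_fit
        h = inv.posterior_.meta["noise_log_precision"]
        assert len(h) == 6 and np.all(np.isfinite(h))

    def test_explained_variance_reported_per_region(self, quick_fit):
        inv, _ = quick_fit
        assert set(inv.explained_variance_) == {
            "lM1", "lPMd", "lSMA", "rM1", "rPMd", "rSMA"}
        assert all(np.isfinite(v) for v in inv.explained_variance_.values())

    def test_data_at_prior_mean_recovers_prior_mean(self, small_inputs):
        # the prior-mean model predicts exactly zero signal
        y = np.zeros((small_inputs.n_scans, 6))
        inv = DCMInverter(variant="m1",
                          settings=InversionSettings(max_iterations=4))
        inv.fit(small_inputs, y)
        assert np.isfinite(inv.free_energy_)
        assert np.abs(inv.posterior_.mean).max() < 0.05

    def test_nonfinite_data_rejected(self, small_inputs):
        y = np.full((small_inputs.n_scans, 6), np.nan)
        with pytest.raises(ValueError):
            DCMInverter().fit(small_inputs, y)


class TestReestimation:
    def test_restart_from_prior_mean_changes_nothing(self, small_inputs,
                                                     neg_template):
        from motordcm.cohort import NoiseSpec, simulate_subject_timeseries

        y = simulate_subject_timeseries(neg_template, small_inputs,
                                        NoiseSpec("white", 1.0), seed=3)
        s = InversionSettings(max_iterations=4)
        base = DCMInverter(variant="m1", settings=s).fit(small_inputs, y)
        priors = default_priors("m1")
        restarted = DCMInverter(variant="m1", settings=s,
                                reestimate_from=priors.mean).fit(small_inputs, y)
        assert restarted.free_energy_ == pytest.approx(base.free_energy_)

    def test_returned_fit_is_the_higher_f_candidate(self, small_inputs,
                                                    neg_template):
        from motordcm.cohort import NoiseSpec, simulate_subject_timeseries
        from motordcm.inversion import reestimate_from_start, variational_laplace

        y = simulate_subject_timeseries(neg_template, small_inputs,
                                        NoiseSpec("white", 1.0), seed=4)
        s = InversionSettings(max_iterations=4)
        priors = default_priors("m1")
        default_fit = variational_laplace(y, small_inputs, priors, settings=s)
        # start at the generating parameter values
        start = priors.mean.copy()
        for i, n in enumerate(priors.names):
            if not n.startswith("offset_"):
                start[i] = neg_template.get_parameter(n)
        best = reestimate_from_start(y, small_inputs, priors, start, settings=s)
        assert best.free_energy >= default_fit.free_energy - 1e-9


class TestExplainedVariance:
    def test_noiseless_data_near_100(self, small_inputs, neg_template):
        from motordcm.integrate import integrate_forward

        y = integrate_forward(neg_template, small_inputs)
        priors = default_priors("m1")
        fwd = DCMForward(small_inputs, priors.names)
        theta = priors.mean.copy()
        for i, n in enumerate(priors.names):
            if not n.startswith("offset_"):
                theta[i] = neg_template.get_parameter(n)
        post = GaussianDensity(priors.names, theta,
                               np.zeros((len(priors), len(priors))))
        ev = explained_variance(post, fwd, y)
        assert all(v > 99.9 for v in ev.values())

    def test_zero_prediction_on_pure_noise_near_zero(self, small_inputs):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(small_inputs.n_scans, 6))
        priors = default_priors("m1")
        fwd = DCMForward(small_inputs, priors.names)
        post = GaussianDensity(priors.names, priors.mean,
                               np.zeros((len(priors), len(priors))))
        ev = explained_variance(post, fwd, y)
        # near zero on the 0-100 scale (chance level at ~50 scans)
        assert all(abs(v) < 35 for v in ev.values())

    def test_zero_variance_column_reported_missing(self, small_inputs):
        y = np.zeros((small_inputs.n_scans, 6))
        priors = default_priors("m1")
        fwd = DCMForward(small_inputs, priors.names)
        post = GaussianDensity(priors.names, priors.mean,
                               np.zeros((len(priors), len(priors))))
        ev = explained_variance(post, fwd, y)
        assert all(np.isnan(v) for v in ev.values())


class TestCompareEvidence:
    def test_equal_evidence_splits_evenly(self):
        out = compare_evidence([0.0, 0.0])
        assert out["probabilities"] == pytest.approx([0.5, 0.5])

    def test_headline_bayes_factor_is_decisive(self):
        out = compare_evidence([2.584e4, 0.0])
        assert round(out["probabilities"][0], 2) == 1.00
        assert out["log_bayes_factors"][0][1] == pytest.approx(2.584e4)

    def test_shift_invariance(self):
        a = compare_evidence([3.0, 1.0, -2.0])["probabilities"]
        b = compare_evidence([103.0, 101.0, 98.0])["probabilities"]
        assert a == pytest.approx(b)

    def test_odds_arithmetic(self):
        out = compare_evidence([np.log(19.0), 0.0])
        assert out["probabilities"][0] == pytest.approx(0.95)

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            compare_evidence([1.0])
        with pytest.raises(ValueError):
            compare_evidence([np.nan, 0.0])
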