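"""Group-level inference: design, PEB fit, BMR, model space, search."""
import numpy as np
import pytest

from motordcm.gaussian import GaussianDensity
from motordcm.peb import (FIELD_SETS, GroupDesign, bayesian_model_reduction,
                          build_design, compare_model_space, fit_group_model,
                          greedy_search_and_average, parameter_probability,
                          _bmr_gaussian)

#: group structure used across the recovery-style tests
AVERAGES = {"A_lSMA->lM1": 0.3, "A_lPMd->lM1": 0.3, "A_lSMA->rM1": 0.35,
            "A_lPMd->rM1": 0.3, "A_lM1->rM1": -0.15, "A_lSMA->rSMA": 0.2,
            "A_lPMd->rPMd": 0.2}
DELTAS = {"A_lSMA->rM1": -0.65, "A_lPMd->rM1": -0.6, "A_lM1->rM1": 0.3}


@pytest.fixture(scope="module")
def fitted_group(synthetic_posterior_factory):
    posts, labels, ages, amps, priors = synthetic_posterior_factory(
        40, seed=7, averages=AVERAGES, deltas=DELTAS)
    design = build_design(ages, labels, amps)
    model = fit_group_model(posts, design, priors)
    return model, posts, labels, priors


class TestBuildDesign:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.ages = rng.uniform(20, 80, 30)
        self.groups = ["negative" if x < 0.5 else "positive"
                       for x in rng.random(30)]
        self.amps = rng.normal(0, 3, 30)

    def test_columns_mutually_orthogonal(self):
        X = build_design(self.ages, self.groups, self.amps).matrix
        G = X.T @ X
        off = G - np.diag(np.diag(G))
        norms = np.sqrt(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.outer(norms, norms).max()

    def test_constant_column_is_all_ones(self):
        X = build_design(self.ages, self.groups, self.amps).matrix
        assert np.all(X[:, 0] == 1.0)

    def test_group_column_two_values_summing_to_zero(self):
        X = build_design(self.ages, self.groups, self.amps).matrix
        assert len(np.unique(np.round(X[:, 1], 12))) == 2
        assert X[:, 1].sum() == pytest.approx(0.0, abs=1e-10)

    def test_age_column_matches_least_squares_residual(self):
        # independent residualisation oracle: regress age on [1, group]
        X = build_design(self.ages, self.groups, self.amps).matrix
        g = np.array([1.0 if s == "negative" else 0.0 for s in self.groups])
        Z = np.column_stack([np.ones_like(g), g])
        beta, *_ = np.linalg.lstsq(Z, self.ages, rcond=None)
        resid = self.ages - Z @ beta
        assert X[:, 2] == pytest.approx(resid, abs=1e-8)
        assert abs(np.corrcoef(X[:, 2], X[:, 1])[0, 1]) < 1e-8

    def test_degenerate_covariate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            build_design(np.full(30, 50.0), self.groups, self.amps)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            build_design([20, 30], ["negative", "positive"], [1.0, -1.0])


class TestFitGroupModel:
    def test_identical_subjects_constant_design(self, synthetic_posterior_factory):
        posts, *_, priors = synthetic_posterior_factory(
            8, seed=1, averages=AVERAGES, between_sd=0.0, deltas={})
        shared = posts[0]
        design = GroupDesign(np.ones((8, 1)), labels=("mean",))
        model = fit_group_model([shared] * 8, design, priors)
        for j, name in enumerate(model.parameter_names):
            assert model.beta.mean[j] == pytest.approx(
                shared.mean[shared.index(name)], abs=0.02)

    def test_kronecker_layout(self, fitted_group):
        model, *_ = fitted_group
        assert len(model.beta.names) == 4 * model.n_parameters
        assert model.beta.names[0].startswith("mean:")

    def test_group_difference_recovered(self, fitted_group):
        model, *_ = fitted_group
        i = model.beta_index("group", "A_lSMA->rM1")
        sd = np.sqrt(model.beta.cov[i, i])
        assert abs(model.beta.mean[i] - DELTAS["A_lSMA->rM1"]) < 2 * sd + 0.05

    def test_component_variances_nonnegative(self, fitted_group):
        model, *_ = fitted_group
        assert set(model.components) == {"A", "C", "decay", "transit"}
        assert all(v >= 0 for v in model.components.values())

    def test_inconsistent_parameter_sets_rejected(self, fitted_group):
        model, posts, _, priors = fitted_group
        bad = GaussianDensity(["x"], [0.0], [[1.0]])
        with pytest.raises(ValueError):
            fit_group_model([posts[0], bad], model.design, priors)

    def test_sign_recovery_across_cohorts(self, synthetic_posterior_factory):
        """The group-difference coefficient keeps the generating sign in
        at least 9 of 10 independently seeded 50-subject cohorts."""
        hits = 0
        for rep in range(10):
            posts, labels, ages, amps, priors = synthetic_posterior_factory(
                50, seed=100 + rep, deltas={"A_lSMA->rM1": 0.3})
            model = fit_group_model(
                posts, build_design(ages, labels, amps), priors)
            i = model.beta_index("group", "A_lSMA->rM1")
            hits += model.beta.mean[i] > 0
        assert hits >= 9


class TestBayesianModelReduction:
    def _toy(self, seed=1):
        rng = np.random.default_rng(seed)
        n, p = 30, 3
        X = rng.normal(size=(n, p))
        sigma2 = 0.5
        y = X @ np.array([1.0, 0.0, -0.5]) + rng.normal(scale=np.sqrt(sigma2),
                                                        size=n)
        def fit(pv):
            P = X.T @ X / sigma2 + np.diag(1.0 / pv)
            S = np.linalg.inv(P)
            m = S @ (X.T @ y / sigma2)
            from scipy.stats import multivariate_normal
            Cy = X @ np.diag(pv) @ X.T + sigma2 * np.eye(n)
            return m, S, multivariate_normal(np.zeros(n), Cy).logpdf(y)
        return fit

    def test_identity_reduction_changes_nothing(self):
        fit = self._toy()
        m, S, _ = fit(np.full(3, 2.0))
        post = GaussianDensity(list("abc"), m, S)
        prior = GaussianDensity.diagonal(list("abc"), np.zeros(3), np.full(3, 2.0))
        dF, reduced = _bmr_gaussian(post, prior, prior)
        assert dF == pytest.approx(0.0, abs=1e-10)
        assert reduced.mean == pytest.approx(m)

    def test_matches_direct_refit(self):
        fit = self._toy()
        pv_full = np.full(3, 2.0)
        pv_red = np.array([2.0, 1e-8, 2.0])
        m, S, F_full = fit(pv_full)
        m_r, S_r, F_red = fit(pv_red)
        post = GaussianDensity(list("abc"), m, S)
        prior = GaussianDensity.diagonal(list("abc"), np.zeros(3), pv_full)
        red = GaussianDensity.diagonal(list("abc"), np.zeros(3), pv_red)
        dF, reduced = _bmr_gaussian(post, prior, red)
        assert dF == pytest.approx(F_red - F_full, abs=1e-4)
        assert reduced.mean == pytest.approx(m_r, abs=1e-8)
        assert reduced.cov == pytest.approx(S_r, abs=1e-8)

    def test_pruning_null_effect_gains_evidence(self):
        fit = self._toy()
        m, S, _ = fit(np.full(3, 2.0))
        post = GaussianDensity(list("abc"), m, S)
        prior = GaussianDensity.diagonal(list("abc"), np.zeros(3), np.full(3, 2.0))
        red = GaussianDensity.diagonal(list("abc"), np.zeros(3),
                                       [2.0, 1e-8, 2.0])  # b is null
        dF, _ = _bmr_gaussian(post, prior, red)
        assert dF > 0

    def test_widened_prior_rejected(self):
        prior = GaussianDensity.diagonal(list("ab"), np.zeros(2), [1.0, 1.0])
        post = GaussianDensity.diagonal(list("ab"), np.zeros(2), [0.5, 0.5])
        wide = GaussianDensity.diagonal(list("ab"), np.zeros(2), [2.0, 1.0])
        with pytest.raises(ValueError, match="unsupported"):
            _bmr_gaussian(post, prior, wide)


class TestModelSpace:
    def test_grid_enumerates_64_models(self, fitted_group):
        model, *_ = fitted_group
        space = compare_model_space(model)
        assert space["free_energy"].shape == (8, 8)
        assert space["probability"].size == 64
        assert len(FIELD_SETS) == 8

    def test_probabilities_sum_to_one(self, fitted_group):
        model, *_ = fitted_group
        space = compare_model_space(model)
        assert space["probability"].sum() == pytest.approx(1.0)

    def test_shift_invariance_of_probabilities(self, fitted_group):
        from scipy.special import softmax

        model, *_ = fitted_group
        F = compare_model_space(model)["free_energy"]
        assert softmax(F.ravel()) == pytest.approx(softmax(F.ravel() + 123.0))

    def test_a_only_effects_select_a_sets(self, fitted_group):
        model, *_ = fitted_group  # effects exist only in A parameters
        space = compare_model_space(model)
        a, d = np.unravel_index(space["probability"].argmax(), (8, 8))
        assert "A" in space["average_sets"][a]
        assert "A" in space["difference_sets"][d]


class TestGreedySearch:
    def test_null_effects_fully_pruned(self, synthetic_posterior_factory):
        # identical subjects: every apparent group difference is noise
        posts, labels, ages, amps, priors = synthetic_posterior_factory(
            30, seed=5, between_sd=0.0)
        model = fit_group_model(posts, build_design(ages, labels, amps), priors)
        cand = [model.beta_index("group", n) for n in model.parameter_names]
        out = greedy_search_and_average(model, candidates=cand)
        assert len(out["pruned"]) == len(cand)

    def test_null_effects_mostly_pruned_with_subject_variability(
            self, synthetic_posterior_factory):
        posts, labels, ages, amps, priors = synthetic_posterior_factory(
            30, seed=5, between_sd=0.05)
        model = fit_group_model(posts, build_design(ages, labels, amps), priors)
        cand = [model.beta_index("group", n) for n in model.parameter_names]
        out = greedy_search_and_average(model, candidates=cand)
        assert len(out["pruned"]) >= 0.9 * len(cand)

    def test_strong_effect_survives(self, fitted_group):
        model, *_ = fitted_group
        out = greedy_search_and_average(
            model, candidates=[model.beta_index("group", n)
                               for n in model.parameter_names])
        i = model.beta_index("group", "A_lSMA->rM1")
        assert i not in out["pruned"]

    def test_average_weights_sum_to_one(self, fitted_group):
        model, *_ = fitted_group
        out = greedy_search_and_average(
            model, candidates=[model.beta_index("group", n)
                               for n in model.parameter_names])
        assert sum(out["weights"]) == pytest.approx(1.0)
        assert isinstance(out["average"], GaussianDensity)


class TestParameterProbability:
    def test_strong_effect_probably_present(self, fitted_group):
        model, *_ = fitted_group
        i = model.beta_index("group", "A_lSMA->rM1")
        assert parameter_probability(model, i) > 0.99

    def test_probability_monotone_in_evidence_gap(self, fitted_group):
        model, *_ = fitted_group
        probs = [parameter_probability(model, model.beta_index("group", n))
                 for n in ("A_lSMA->rM1", "A_rM1->lM1")]
        # the engineered effect dominates an unstructured connection
        assert probs[0] > probs[1]

    def test_out_of_range_index_rejected(self, fitted_group):
        model, *_ = fitted_group
        with pytest.raises(IndexError):
            parameter_probability(model, 10 ** 6)
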