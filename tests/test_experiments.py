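"""Virtual perturbations: sweeps, sign flips, peak metrics, regression."""
import numpy as np
import pandas as pd
import pytest

from motordcm.experiments import (connection_amplitude_regression,
                                  flipping_parameters, peak_metrics,
                                  perturb_and_predict, sign_flip_set)
from motordcm.integrate import volterra_kernel
from motordcm.model import SubjectModel

HEADLINE = ("A_lM1->rM1", "A_lPMd->rM1", "A_lSMA->rM1")


def _extrema_by_offset(table: pd.DataFrame) -> np.ndarray:
    out = []
    for _, grp in table.groupby("offset", sort=True):
        v = grp["signal"].to_numpy()
        out.append(v[np.argmax(np.abs(v))])
    return np.array(out)


class TestPerturbAndPredict:
    def test_zero_offset_reproduces_base_kernel(self, neg_template):
        fam = perturb_and_predict(neg_template, "A_lSMA->rM1", [0.0])
        base = volterra_kernel(neg_template, "AV")["rM1"].to_numpy()
        assert np.array_equal(fam["signal"].to_numpy(), base)

    @pytest.mark.parametrize("connection", HEADLINE)
    def test_extremum_monotone_in_interhemispheric_offsets(self, neg_template,
                                                           connection):
        fam = perturb_and_predict(neg_template, connection,
                                  np.linspace(-1, 1, 9))
        ext = _extrema_by_offset(fam)
        assert np.all(np.diff(ext) >= -1e-9)

    def test_transit_sweep_changes_amplitude_not_sign(self, neg_template):
        fam = perturb_and_predict(neg_template, "transit_rM1",
                                  np.linspace(-1, 1, 5))
        ext = _extrema_by_offset(fam)
        assert np.all(np.sign(ext) == -1)
        assert ext.max() - ext.min() != 0.0

    def test_unknown_parameter_rejected(self, neg_template):
        with pytest.raises(KeyError):
            perturb_and_predict(neg_template, "A_nope->rM1", [0.0])


class TestSignFlipSet:
    @pytest.fixture(scope="class")
    def negative_flips(self, neg_template):
        return sign_flip_set(neg_template,
                             parameters=list(HEADLINE) +
                             ["transit_rM1", "decay", "A_rSMA->rM1"])

    def test_interhemispheric_connections_flip(self, negative_flips):
        assert set(HEADLINE) <= set(flipping_parameters(negative_flips))

    def test_haemodynamic_parameters_do_not_flip(self, negative_flips):
        flips = flipping_parameters(negative_flips)
        assert "transit_rM1" not in flips and "decay" not in flips

    def test_flip_offsets_refined(self, negative_flips):
        for r in negative_flips:
            if r.flips:
                assert r.flip_offset is not None
                assert -1.0 <= r.flip_offset <= 1.0

    def test_positive_base_flips_back(self, pos_template):
        res = sign_flip_set(pos_template, parameters=list(HEADLINE))
        assert set(HEADLINE) <= set(flipping_parameters(res))

    def test_flip_set_stable_under_grid_refinement(self, neg_template):
        params = list(HEADLINE) + ["transit_rM1"]
        coarse = sign_flip_set(neg_template, parameters=params, n_offsets=21)
        fine = sign_flip_set(neg_template, parameters=params, n_offsets=41)
        assert flipping_parameters(coarse) == flipping_parameters(fine)

    def test_indeterminate_base_sign_rejected(self):
        silent = SubjectModel.zeros()  # no drive anywhere: no response
        with pytest.raises(ValueError, match="sign"):
            sign_flip_set(silent, parameters=["A_lSMA->rM1"])


class TestPeakMetrics:
    def test_synthetic_bump(self):
        t = np.arange(0, 20, 0.5)
        k = pd.Series(np.exp(-0.5 * (t - 6.0) ** 2), index=t)
        out = peak_metrics(k)
        assert out["amplitude"] == pytest.approx(1.0)
        assert out["latency_s"] == 6.0
        assert out["latency_rounded_s"] == 6.0

    def test_negation_symmetry(self):
        t = np.arange(0, 20, 0.5)
        k = pd.Series(np.exp(-0.5 * (t - 6.0) ** 2), index=t)
        a, b = peak_metrics(k), peak_metrics(-k)
        assert b["amplitude"] == -a["amplitude"]
        assert b["latency_s"] == a["latency_s"]

    def test_half_second_rounding_is_half_up(self):
        k = pd.Series([0.0, 1.0], index=[0.0, 5.26])
        assert peak_metrics(k)["latency_rounded_s"] == 5.5
        k = pd.Series([0.0, 1.0], index=[0.0, 5.24])
        assert peak_metrics(k)["latency_rounded_s"] == 5.0

    def test_ties_break_toward_earlier_time(self):
        k = pd.Series([0.0, 1.0, -1.0], index=[0.0, 2.0, 4.0])
        assert peak_metrics(k)["latency_s"] == 2.0

    def test_all_zero_kernel_reported_missing(self):
        out = peak_metrics(pd.Series(np.zeros(5), index=np.arange(5.0)))
        assert np.isnan(out["amplitude"]) and np.isnan(out["latency_s"])

    def test_empty_kernel_rejected(self):
        with pytest.raises(ValueError):
            peak_metrics(pd.Series(dtype=float))


class TestConnectionAmplitudeRegression:
    def test_exact_linear_relationship(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        out = connection_amplitude_regression({"c": x}, 2.0 * x + 1.0)
        assert out["single"]["c"]["R2"] == pytest.approx(1.0)
        assert out["joint_R2"] == pytest.approx(1.0)

    def test_independent_noise_explains_little(self):
        rng = np.random.default_rng(1)
        out = connection_amplitude_regression(
            {"c": rng.normal(size=500)}, rng.normal(size=500))
        assert out["single"]["c"]["R2"] < 0.02

    def test_joint_model_matches_normal_equations(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 2))
        X[:, 1] += 0.5 * X[:, 0]  # correlated predictors
        y = 1.0 * X[:, 0] - 0.5 * X[:, 1] + rng.normal(size=80)
        out = connection_amplitude_regression({"a": X[:, 0], "b": X[:, 1]}, y)
        # brute-force normal-equations oracle
        Z = np.column_stack([np.ones(80), X])
        beta = np.linalg.solve(Z.T @ Z, Z.T @ y)
        resid = y - Z @ beta
        r2 = 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert out["joint_R2"] == pytest.approx(r2, abs=1e-10)
        assert out["joint_R2"] >= max(out["single"]["a"]["R2"],
                                      out["single"]["b"]["R2"])

    def test_single_predictor_r_is_pearson(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        y = 0.7 * x + rng.normal(size=60)
        out = connection_amplitude_regression({"c": x}, y)
        assert out["single"]["c"]["R"] == pytest.approx(
            np.corrcoef(x, y)[0, 1])
        assert out["single"]["c"]["R2"] == pytest.approx(
            out["single"]["c"]["R"] ** 2)

    def test_degenerate_predictor_flagged(self):
        out = connection_amplitude_regression(
            {"flat": np.ones(10), "ok": np.arange(10.0)}, np.arange(10.0))
        assert out["single"]["flat"]["degenerate"]
        assert np.isnan(out["single"]["flat"]["R"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            connection_amplitude_regression({"c": np.arange(5.0)}, np.arange(4.0))
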