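"""Shared fixtures: compact designs and the expensive fitted cohorts.

The heavy fixtures (a 20-subject inverted cohort and a small end-to-end
pipeline run) are session-scoped so several tests can share one
computation.  Problem sizes are deliberately smaller than the
full-scale study (fewer trials, shorter sessions) while keeping the
statistical structure intact.
"""
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from motordcm.cohort import (CohortSpec, NoiseSpec, negative_responder_template,
                             positive_responder_template, sample_cohort,
                             simulate_subject_timeseries)
from motordcm.design import generate_design, rasterize_inputs
from motordcm.inversion import DCMInverter
from motordcm.vl import InversionSettings


@pytest.fixture(scope="session")
def small_design():
    return generate_design(3, 1, 1, (2.0, 10.0), seed=7)


@pytest.fixture(scope="session")
def small_inputs(small_design):
    n_scans = int(np.ceil((small_design.trials[-1].onset + 28.0) / 2.0))
    return rasterize_inputs(small_design, n_scans, 16, 2.0)


@pytest.fixture(scope="session")
def neg_template():
    return negative_responder_template()


@pytest.fixture(scope="session")
def pos_template():
    return positive_responder_template()


@pytest.fixture(scope="session")
def recovery_fits():
    """20 synthetic subjects at snr 1, each inverted under the m1 priors.

    Returns the generating subjects, their posteriors and the shared
    input matrix; reused by the coverage, rank-correlation and
    explained-variance tests.
    """
    design = generate_design(4, 1, 1, (2.0, 10.0), seed=21)
    n_scans = int(np.ceil((design.trials[-1].onset + 28.0) / 2.0))
    inputs = rasterize_inputs(design, n_scans, 16, 2.0)
    spec = CohortSpec(n_subjects=20, seed=33, noise=NoiseSpec("white", snr=1.0))
    cohort = sample_cohort(spec)
    settings_ = InversionSettings(max_iterations=32)
    inverters = []
    for i, subj in enumerate(cohort.subjects):
        y = simulate_subject_timeseries(subj, inputs, spec.noise, seed=1000 + i)
        inverters.append(DCMInverter(variant="m1", settings=settings_).fit(inputs, y))
    return {"cohort": cohort, "inverters": inverters, "inputs": inputs}


def make_synthetic_posteriors(n_subjects, seed, averages=None, deltas=None,
                              between_sd=0.1, posterior_scale=0.05):
    """Subject posteriors drawn around group-structured parameter means.

    Emulates the output of per-subject inversion for group-level tests:
    each subject's posterior mean is a group template (averages +/-
    deltas for negative responders) plus between-subject noise, and the
    posterior covariance is a fixed fraction of the prior covariance.
    Returns (posteriors, group labels, ages, amplitudes, priors).
    """
    from motordcm.cohort import PRINTED_MIXTURE_COVS, PRINTED_MIXTURE_MEANS
    from motordcm.gaussian import GaussianDensity
    from motordcm.inversion import default_priors

    priors = default_priors("m1")
    names = priors.names
    free = priors.variances > 0
    rng = np.random.default_rng(seed)
    groups = rng.random(n_subjects) < 0.46
    averages = averages or {}
    deltas = deltas or {}
    posteriors, ages, amps = [], [], []
    for i in range(n_subjects):
        mu = np.zeros(len(names))
        for k, name in enumerate(names):
            if not free[k] or name.startswith("offset_"):
                continue
            mu[k] = averages.get(name, 0.0) \
                + (deltas.get(name, 0.0) if groups[i] else 0.0) \
                + between_sd * rng.normal()
        cov = np.zeros((len(names), len(names)))
        cov[np.ix_(free, free)] = np.diag(priors.variances[free] * posterior_scale)
        posteriors.append(GaussianDensity(names, mu, cov, free_energy=0.0))
        comp = 0 if groups[i] else 1
        age, amp = rng.multivariate_normal(PRINTED_MIXTURE_MEANS[comp],
                                           PRINTED_MIXTURE_COVS[comp])
        ages.append(age)
        amps.append(amp)
    labels = ["negative" if g else "positive" for g in groups]
    return posteriors, labels, np.array(ages), np.array(amps), priors


@pytest.fixture(scope="session")
def synthetic_posterior_factory():
    return make_synthetic_posteriors


@pytest.fixture(scope="session")
def pipeline_report(tmp_path_factory):
    """A small but complete end-to-end synthetic study."""
    from motordcm.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(seed=11, out_dir=str(out), n_per_tone=3,
                         n_audio_only=1, n_visual_only=1, n_scans=48,
                         n_subjects=8, max_iterations=24)
    report = run_pipeline(cfg)
    return {"config": cfg, "report": report, "out": out}
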