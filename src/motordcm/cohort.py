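"""Synthetic cohorts: subject parameters, covariates and noisy BOLD data.

The real study population cannot be redistributed, so this module
generates cohorts with the statistical structure the analysis assumes:

* each subject belongs to a *negative responder* or *positive responder*
  group (responding to the sign of their ipsilateral-M1 BOLD response);
* (age, rM1 amplitude) covariates follow a two-component 2D Gaussian
  mixture — the negative responders younger with negative amplitudes,
  the positive responders older with positive ones;
* group differences in effective connectivity are concentrated on the
  inter-hemispheric connections into rM1 (lSMA→rM1, lPMd→rM1, lM1→rM1),
  on top of within-group parameter variability;
* observed timeseries are the forward model's prediction plus white or
  AR(1) noise at a configurable signal-to-noise ratio.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import InputMatrix
from .integrate import integrate_forward
from .model import REGIONS, SubjectModel

__all__ = [
    "PRINTED_MIXTURE_WEIGHTS",
    "PRINTED_MIXTURE_MEANS",
    "PRINTED_MIXTURE_COVS",
    "NoiseSpec",
    "CohortSpec",
    "Cohort",
    "negative_responder_template",
    "positive_responder_template",
    "sample_printed_mixture",
    "sample_cohort",
    "simulate_subject_timeseries",
    "make_roster",
    "apply_exclusions",
]

# Two-component mixture over (age [years], rM1 amplitude [a.u.]):
# component 0 = negative responders (younger, negative BOLD),
# component 1 = positive responders (older, positive BOLD).
PRINTED_MIXTURE_WEIGHTS = np.array([0.46, 0.54])
PRINTED_MIXTURE_MEANS = np.array([[44.77, -3.53], [62.07, 4.51]])
PRINTED_MIXTURE_COVS = np.array([
    [[289.71, -11.16], [-11.16, 5.20]],
    [[238.31, -12.43], [-12.43, 8.12]],
])
GROUP_LABELS = ("negative", "positive")


def sample_printed_mixture(n: int, seed: int = 0,
                           return_components: bool = False):
    """Draw (age, rM1 amplitude) pairs from the two-component mixture.

    Components are chosen with the mixture weights (0.46/0.54); each
    component is a full-covariance 2D Gaussian.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(2, size=n, p=PRINTED_MIXTURE_WEIGHTS)
    pts = np.empty((n, 2))
    for k in range(2):
        m = comp == k
        if m.any():
            pts[m] = rng.multivariate_normal(
                PRINTED_MIXTURE_MEANS[k], PRINTED_MIXTURE_COVS[k], size=int(m.sum()))
    if return_components:
        return pts, comp
    return pts


# ---------------------------------------------------------------------------
# responder templates
# ---------------------------------------------------------------------------

def positive_responder_template() -> SubjectModel:
    """Typical older subject: net excitatory drive into rM1.

    Left SMA and PMd receive the task input; activity spreads within the
    left hemisphere and crosses to the right hemisphere with positive
    lSMA→rM1 and lPMd→rM1 coupling and a weak negative lM1→rM1 edge.
    """
    m = SubjectModel.zeros()
    for name, value in {
        "C_lSMA_AV": 0.6, "C_lSMA_A": 0.6, "C_lSMA_V": 0.6,
        "C_lPMd_AV": 0.6, "C_lPMd_A": 0.6, "C_lPMd_V": 0.6,
        "A_lSMA->lM1": 0.30, "A_lPMd->lM1": 0.30, "A_lSMA->lPMd": 0.10,
        "A_lSMA->rSMA": 0.20, "A_lPMd->rPMd": 0.20,
        "A_rSMA->rM1": 0.10, "A_rPMd->rM1": 0.10,
        "A_lSMA->rM1": 0.35, "A_lPMd->rM1": 0.30, "A_lM1->rM1": -0.15,
    }.items():
        m.set_parameter(name, value)
    return m


#: group differences (negative minus positive responders) on the three
#: headline inter-hemispheric connections into rM1
DEFAULT_GROUP_DELTAS = {
    "A_lSMA->rM1": -0.65,
    "A_lPMd->rM1": -0.60,
    "A_lM1->rM1": +0.30,
}


def negative_responder_template() -> SubjectModel:
    """Typical younger subject: net inhibitory drive into rM1."""
    m = positive_responder_template()
    for name, delta in DEFAULT_GROUP_DELTAS.items():
        m.set_parameter(name, m.get_parameter(name) + delta)
    return m


# ---------------------------------------------------------------------------
# cohort specification and sampling
# ---------------------------------------------------------------------------

@dataclass
class NoiseSpec:
    """Observation noise: white or AR(1), scaled by signal-to-noise ratio.

    ``snr`` is the ratio of per-region signal SD to noise SD;
    ``snr=inf`` yields the noiseless forward prediction.
    """

    model: str = "ar1"
    snr: float = 1.0
    ar_coefficient: float = 0.2

    def __post_init__(self) -> None:
        if self.model not in ("white", "ar1"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if self.model == "ar1" and not -1.0 < self.ar_coefficient < 1.0:
            raise ValueError("AR coefficient must lie in (-1, 1)")


@dataclass
class CohortSpec:
    """Everything needed to draw a reproducible synthetic cohort."""

    n_subjects: int
    seed: int
    group_deltas: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_DELTAS))
    base_template: SubjectModel | None = None  # positive-responder template
    between_subject_sd: dict[str, float] = field(default_factory=lambda: {
        "A": 0.10, "C": 0.10, "selfA": 0.05, "decay": 0.05, "transit": 0.05})
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    group_weights: tuple[float, float] = (
        float(PRINTED_MIXTURE_WEIGHTS[0]), float(PRINTED_MIXTURE_WEIGHTS[1]))

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        template = self.base_template or positive_responder_template()
        valid = set(template.parameter_names())
        unknown = set(self.group_deltas) - valid
        if unknown:
            raise ValueError(f"group_deltas name unknown parameters: {sorted(unknown)}")


@dataclass
class Cohort:
    subjects: list[SubjectModel]
    groups: list[str]
    covariates: pd.DataFrame  # subject_id, age, rm1_amplitude, group


def _field_of(name: str) -> str:
    if name == "decay":
        return "decay"
    return name.split("_", 1)[0]


def sample_cohort(spec: CohortSpec) -> Cohort:
    """Draw subject parameter sets, group labels and covariates.

    Group membership follows ``group_weights``; negative responders get
    the positive-responder template shifted by ``group_deltas`` (so the
    population mean difference, negative minus positive, equals each
    delta exactly); every free parameter then receives independent
    Gaussian between-subject variation with the per-field SDs.
    Covariates are drawn from the corresponding component of the
    printed (age, rM1 amplitude) mixture.
    """
    rng = np.random.default_rng(spec.seed)
    pos = spec.base_template.copy() if spec.base_template else positive_responder_template()
    neg = pos.copy()
    for name, delta in spec.group_deltas.items():
        neg.set_parameter(name, neg.get_parameter(name) + delta)
    templates = {"negative": neg, "positive": pos}

    groups = [GROUP_LABELS[k] for k in
              rng.choice(2, size=spec.n_subjects, p=spec.group_weights)]
    subjects: list[SubjectModel] = []
    rows = []
    for i, g in enumerate(groups):
        subj = templates[g].copy()
        for name in subj.parameter_names():
            sd = spec.between_subject_sd.get(name,
                                             spec.between_subject_sd.get(_field_of(name), 0.0))
            if sd > 0:
                subj.set_parameter(name, subj.get_parameter(name) + sd * rng.normal())
        subjects.append(subj)
        k = GROUP_LABELS.index(g)
        age, amp = rng.multivariate_normal(PRINTED_MIXTURE_MEANS[k],
                                           PRINTED_MIXTURE_COVS[k])
        rows.append({"subject_id": f"sub-{i:03d}", "age": age,
                     "rm1_amplitude": amp, "group": g})
    covariates = pd.DataFrame(rows)
    return Cohort(subjects, groups, covariates)


def simulate_subject_timeseries(
    model: SubjectModel,
    inputs: InputMatrix,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Forward prediction per scan plus realised observation noise.

    With ``snr=inf`` (or ``noise=None``) returns the forward prediction
    exactly.  Noise SD per region is that region's prediction SD divided
    by ``snr``; AR(1) noise is scaled to the same marginal SD.
    """
    pred = integrate_forward(model, inputs)
    if noise is None or not np.isfinite(noise.snr):
        return pred
    rng = np.random.default_rng(seed)
    V, R = pred.shape
    sd = pred.to_numpy().std(axis=0) / noise.snr
    if noise.model == "white":
        e = rng.normal(size=(V, R)) * sd
    else:
        a = noise.ar_coefficient
        w = rng.normal(size=(V, R)) * (sd * np.sqrt(1.0 - a * a))
        e = np.empty((V, R))
        e[0] = rng.normal(size=R) * sd
        for t in range(1, V):
            e[t] = a * e[t - 1] + w[t]
    return pred + e


# ---------------------------------------------------------------------------
# roster bookkeeping
# ---------------------------------------------------------------------------

def make_roster(n_total: int = 652, n_missing_or_dropout: int = 9,
                n_stroke: int = 8, seed: int = 0) -> pd.DataFrame:
    """Synthetic participant roster with exclusion flags.

    Emulates the study's bookkeeping: of the initial sample, a few
    subjects have missing data or signal dropout, and a few have a
    history of stroke; flags never overlap.
    """
    if n_missing_or_dropout + n_stroke > n_total:
        raise ValueError("more exclusions than participants")
    rng = np.random.default_rng(seed)
    flagged = rng.choice(n_total, size=n_missing_or_dropout + n_stroke, replace=False)
    missing = set(flagged[:n_missing_or_dropout].tolist())
    stroke = set(flagged[n_missing_or_dropout:].tolist())
    return pd.DataFrame({
        "subject_id": [f"sub-{i:03d}" for i in range(n_total)],
        "missing_or_dropout": [i in missing for i in range(n_total)],
        "stroke": [i in stroke for i in range(n_total)],
    })


def apply_exclusions(roster: pd.DataFrame) -> pd.DataFrame:
    """Drop flagged participants; returns the analysable sample."""
    for col in ("missing_or_dropout", "stroke"):
        if col not in roster.columns:
            raise ValueError(f"roster lacks required column {col!r}")
    keep = ~(roster["missing_or_dropout"].astype(bool)
             | roster["stroke"].astype(bool))
    return roster.loc[keep].reset_index(drop=True)
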