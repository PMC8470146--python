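"""Hierarchical (parametric empirical Bayes) inference over subjects.

Subject-level posteriors become data for a second-level general linear
model: each parameter is regressed on a between-subject design with four
orthogonal columns (group average, responder-group difference, residual
age, residual rM1 amplitude).  Between-subject variability is modelled
with one variance component per parameter field (A, C, decay, transit),
parameterised by log-precisions.

Each subject's contribution enters as a pseudo-likelihood obtained by
removing the first-level prior from its posterior (posterior precision
minus prior precision), so the hierarchy does not double-count the
prior.  With the second-level coefficients integrated out analytically,
the model evidence is exact given the log-precisions, which are
optimised numerically.

Bayesian model reduction (BMR) re-evaluates evidence and posterior
under a shrunk prior without refitting; it powers the 64-model
field-set comparison, the greedy pruning search with model averaging,
and per-parameter on/off posterior probabilities.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import softmax
from sklearn.base import BaseEstimator

from .gaussian import GaussianDensity

__all__ = [
    "GroupDesign",
    "GroupModel",
    "build_design",
    "default_field_map",
    "HierarchicalGLM",
    "fit_group_model",
    "bayesian_model_reduction",
    "FIELD_SETS",
    "compare_model_space",
    "greedy_search_and_average",
    "parameter_probability",
]

COVARIATES = ("mean", "group", "age", "rm1_amplitude")

#: the eight parameter-field subsets compared at the group level
FIELD_SETS: tuple[tuple[str, ...], ...] = (
    ("A", "C", "transit", "decay"),  # all
    ("A", "C"),
    ("A", "transit", "decay"),
    ("C", "transit", "decay"),
    ("A",),
    ("C",),
    ("transit", "decay"),
    (),                              # none
)

#: prior variance assigned to a switched-off second-level coefficient
REDUCED_VARIANCE = 1e-8


@dataclass
class GroupDesign:
    """N x 4 orthogonalised between-subject design matrix."""

    matrix: np.ndarray
    labels: tuple[str, ...] = COVARIATES
    orthogonalisation: str = "recursive Gram-Schmidt with mean-centring"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.labels):
            raise ValueError("design matrix must have one column per label")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]


def build_design(ages, groups, rm1_amplitudes) -> GroupDesign:
    """Recursive Gram-Schmidt orthogonalisation of the group covariates.

    Column order: constant; mean-centred group indicator (1 = negative
    responder, 0 = positive responder before centring); age residualised
    on the preceding columns; rM1 amplitude residualised on all three.
    The constant column stays all-ones so its coefficients read as the
    group average.
    """
    ages = np.asarray(ages, dtype=float)
    rm1 = np.asarray(rm1_amplitudes, dtype=float)
    groups = np.asarray(
        [1.0 if g in (1, "negative", True) else 0.0 for g in np.asarray(groups).ravel()])
    n = ages.size
    if not (groups.size == n == rm1.size):
        raise ValueError("covariates must have equal lengths")
    if n < 5:
        raise ValueError("need at least 5 subjects for the group design")
    X = np.ones((n, 4))
    for j, col in enumerate((groups, ages, rm1), start=1):
        if np.var(col) == 0:
            raise ValueError(
                f"degenerate design: covariate {COVARIATES[j]!r} has zero variance")
        resid = col - col.mean()
        for k in range(1, j):  # project out previously built columns
            prev = X[:, k]
            resid = resid - prev * (resid @ prev) / (prev @ prev)
        X[:, j] = resid
    return GroupDesign(X)


def default_field_map(names) -> dict[str, str]:
    """Parameter name -> variance-component field.

    Self-connection log-scalers belong to the A field; per-region
    offsets are observation parameters and are excluded (absent).
    """
    out = {}
    for n in names:
        if n.startswith(("A_", "selfA_")):
            out[n] = "A"
        elif n.startswith("C_"):
            out[n] = "C"
        elif n == "decay":
            out[n] = "decay"
        elif n.startswith("transit_"):
            out[n] = "transit"
    return out


@dataclass
class GroupModel:
    """Fitted second-level model over M parameters and K covariates."""

    design: GroupDesign
    parameter_names: list[str]           # M first-level parameters
    beta: GaussianDensity                # posterior over K*M coefficients
    beta_prior: GaussianDensity
    components: dict[str, float]         # field -> between-subject variance scale
    free_energy: float
    field_map: dict[str, str] = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    def beta_index(self, covariate: str, parameter: str) -> int:
        k = list(self.design.labels).index(covariate)
        return k * self.n_parameters + self.parameter_names.index(parameter)

    def coefficient_table(self) -> pd.DataFrame:
        M = self.n_parameters
        rows = []
        for k, cov in enumerate(self.design.labels):
            for j, pname in enumerate(self.parameter_names):
                i = k * M + j
                rows.append({"covariate": cov, "parameter": pname,
                             "mean": self.beta.mean[i],
                             "sd": float(np.sqrt(self.beta.cov[i, i]))})
        return pd.DataFrame(rows)


class HierarchicalGLM(BaseEstimator):
    """Empirical-Bayes group GLM over subject posteriors.

    Parameters
    ----------
    priors : GaussianDensity
        First-level priors shared by all subjects (used to remove the
        prior from each posterior and to scale coefficient priors).
    field_map : dict, optional
        Parameter -> field; parameters absent from the map are excluded
        from the group model.  Defaults to A/C/decay/transit grouping.
    beta_prior_scale : float
        Coefficient prior variance = scale x level-1 prior variance.
    gamma_prior_variance : float
        Variance of the Gaussian hyperprior on field log-precisions.

    Attributes (after ``fit(X, y)`` with X a GroupDesign and y a list of
    subject posteriors): ``model_`` (GroupModel), ``beta_``,
    ``free_energy_``, ``components_``.
    """

    def __init__(self, priors: GaussianDensity, field_map: dict | None = None,
                 beta_prior_scale: float = 1.0, gamma_prior_variance: float = 4.0):
        self.priors = priors
        self.field_map = field_map
        self.beta_prior_scale = beta_prior_scale
        self.gamma_prior_variance = gamma_prior_variance

    def fit(self, X: GroupDesign, y: list[GaussianDensity]) -> "HierarchicalGLM":
        design = X if isinstance(X, GroupDesign) else GroupDesign(np.asarray(X))
        posteriors = list(y)
        if design.n_subjects != len(posteriors):
            raise ValueError("design rows and posterior count differ")
        names0 = posteriors[0].names
        for p in posteriors[1:]:
            if p.names != names0:
                raise ValueError("all subjects must share the same parameter set")

        fmap = self.field_map or default_field_map(names0)
        prior_var_full = dict(zip(self.priors.names, self.priors.variances))
        # group-level parameters: mapped to a field and free at level 1
        names = [n for n in names0
                 if n in fmap and prior_var_full.get(n, 0.0) > 0.0]
        M, K, N = len(names), len(design.labels), design.n_subjects
        if M == 0:
            raise ValueError("no group-level parameters selected")
        fields = sorted({fmap[n] for n in names})
        pv = np.array([prior_var_full[n] for n in names])

        # pseudo-likelihood per subject: remove the first-level prior
        idx0 = [names0.index(n) for n in names]
        prior_sub = self.priors.marginal(names)
        iS0 = np.linalg.inv(prior_sub.cov)
        P_t, m_t = [], []
        for p in posteriors:
            S = p.cov[np.ix_(idx0, idx0)]
            mu = p.mean[idx0]
            Pi = np.linalg.inv(0.5 * (S + S.T))
            Pt = 0.5 * ((Pi - iS0) + (Pi - iS0).T)
            # directions where the posterior is no tighter than the prior
            # carry no first-level information: floor their precision and
            # zero their pseudo-data mean instead of letting it blow up
            w, V = np.linalg.eigh(Pt)
            proj = V.T @ (Pi @ mu - iS0 @ prior_sub.mean)
            informative = w > 1e-8
            mt = V @ np.where(informative, proj / np.where(informative, w, 1.0), 0.0)
            Pt = (V * np.clip(w, 1e-8, None)) @ V.T
            P_t.append(Pt)
            m_t.append(mt)

        # coefficient prior: block-diagonal over covariates
        beta_var = np.tile(pv * self.beta_prior_scale, K)
        Pi_b = np.diag(1.0 / beta_var)
        logdet_Sb0 = float(np.sum(np.log(beta_var)))

        D_field = {f: np.diag([prior_var_full[n] if fmap[n] == f else 0.0
                               for n in names]) for f in fields}
        Xb = design.matrix

        def evidence(gamma: np.ndarray):
            Gamma = sum(np.exp(-g) * D_field[f] for g, f in zip(gamma, fields))
            A = np.zeros((K * M, K * M))
            b = np.zeros(K * M)
            quad = 0.0
            logdetV = 0.0
            for i in range(N):
                Vi = Gamma + np.linalg.inv(P_t[i])
                Wi = np.linalg.inv(0.5 * (Vi + Vi.T))
                sign, ld = np.linalg.slogdet(Vi)
                if sign <= 0:
                    return -np.inf, None, None
                logdetV += ld
                A += np.kron(np.outer(Xb[i], Xb[i]), Wi)
                b += np.kron(Xb[i], Wi @ m_t[i])
                quad += float(m_t[i] @ Wi @ m_t[i])
            Pb = A + Pi_b
            Sb = np.linalg.inv(Pb)
            sign, logdet_Sb = np.linalg.slogdet(Sb)
            if sign <= 0:
                return -np.inf, None, None
            mb = Sb @ b
            F = (-0.5 * (quad - float(b @ mb))
                 - 0.5 * logdetV - 0.5 * N * M * np.log(2 * np.pi)
                 - 0.5 * logdet_Sb0 + 0.5 * logdet_Sb
                 - 0.5 * float(gamma @ gamma) / self.gamma_prior_variance)
            return F, mb, 0.5 * (Sb + Sb.T)

        res = optimize.minimize(
            lambda g: -evidence(g)[0], x0=np.zeros(len(fields)),
            method="L-BFGS-B", bounds=[(-12.0, 12.0)] * len(fields),
            options={"maxiter": 100})
        gamma = res.x
        F, mb, Sb = evidence(gamma)

        beta_names = [f"{cov}:{n}" for cov in design.labels for n in names]
        self.beta_ = GaussianDensity(beta_names, mb, Sb, free_energy=float(F))
        self.beta_prior_ = GaussianDensity.diagonal(
            beta_names, np.zeros(K * M), beta_var)
        self.components_ = {f: float(np.exp(-g)) for f, g in zip(fields, gamma)}
        self.free_energy_ = float(F)
        self.model_ = GroupModel(
            design=design, parameter_names=names, beta=self.beta_,
            beta_prior=self.beta_prior_, components=self.components_,
            free_energy=self.free_energy_, field_map=fmap)
        return self


def fit_group_model(posteriors: list[GaussianDensity], design: GroupDesign,
                    priors: GaussianDensity,
                    field_map: dict | None = None, **kwargs) -> GroupModel:
    """Fit the second-level GLM; see :class:`HierarchicalGLM`."""
    if field_map is not None:
        missing = [n for n in field_map if n not in posteriors[0].names]
        if missing:
            raise ValueError(f"field_map names unknown parameters: {missing}")
    est = HierarchicalGLM(priors, field_map=field_map, **kwargs)
    est.fit(design, posteriors)
    return est.model_


# ---------------------------------------------------------------------------
# Bayesian model reduction
# ---------------------------------------------------------------------------

def _bmr_gaussian(post: GaussianDensity, prior: GaussianDensity,
                  reduced_prior: GaussianDensity) -> tuple[float, GaussianDensity]:
    """Evidence change and posterior under a shrunk prior (analytic)."""
    if np.any(reduced_prior.variances > prior.variances + 1e-12):
        raise ValueError("unsupported reduction: reduced prior wider than full prior")
    P = np.linalg.inv(post.cov)
    P0 = np.linalg.inv(prior.cov)
    P0r = np.linalg.inv(reduced_prior.cov)
    m, m0, m0r = post.mean, prior.mean, reduced_prior.mean
    Pr = P - P0 + P0r
    Sr = np.linalg.inv(Pr)
    mr = Sr @ (P @ m - P0 @ m0 + P0r @ m0r)

    def half_logdet(Mx):
        sign, ld = np.linalg.slogdet(Mx)
        if sign <= 0:
            raise np.linalg.LinAlgError("reduction produced an improper posterior")
        return 0.5 * ld

    dF = (half_logdet(P0r) - half_logdet(Pr) - 0.5 * float(m0r @ P0r @ m0r)
          + 0.5 * float(mr @ Pr @ mr)
          - (half_logdet(P0) - half_logdet(P) - 0.5 * float(m0 @ P0 @ m0)
             + 0.5 * float(m @ P @ m)))
    reduced = GaussianDensity(list(post.names), mr, 0.5 * (Sr + Sr.T))
    return float(dF), reduced


def bayesian_model_reduction(model: GroupModel,
                             reduced_prior: GaussianDensity) -> tuple[float, GaussianDensity]:
    """Re-evaluate the group model under a shrunk coefficient prior.

    Returns (free-energy change relative to the full model, reduced
    posterior over the coefficients) without refitting.
    """
    if reduced_prior.names != model.beta.names:
        raise ValueError("reduced prior must cover the same coefficients")
    return _bmr_gaussian(model.beta, model.beta_prior, reduced_prior)


def _reduced_prior_switch_off(model: GroupModel, off: list[int]) -> GaussianDensity:
    var = model.beta_prior.variances.copy()
    var[off] = REDUCED_VARIANCE
    return GaussianDensity.diagonal(model.beta.names, model.beta_prior.mean, var)


def compare_model_space(model: GroupModel, sets=FIELD_SETS) -> dict:
    """Evidence over the (average-set x difference-set) model grid.

    Every combination of one field subset for the group-average
    coefficients and one for the group-difference coefficients defines a
    candidate reduced model (the residual age and amplitude covariates
    stay on); with the eight canonical subsets this is a 64-model space.
    Returns the free-energy grid and softmax posterior probabilities.
    """
    M = model.n_parameters
    fmap = model.field_map
    k_mean = list(model.design.labels).index("mean")
    k_group = list(model.design.labels).index("group")
    n_sets = len(sets)
    F = np.zeros((n_sets, n_sets))
    for a, avg_set in enumerate(sets):
        for d, diff_set in enumerate(sets):
            off = []
            for j, pname in enumerate(model.parameter_names):
                if fmap[pname] not in avg_set:
                    off.append(k_mean * M + j)
                if fmap[pname] not in diff_set:
                    off.append(k_group * M + j)
            dF, _ = bayesian_model_reduction(
                model, _reduced_prior_switch_off(model, off))
            F[a, d] = dF
    prob = softmax(F.ravel()).reshape(F.shape)
    labels = [" + ".join(s) if s else "none" for s in sets]
    return {"free_energy": F, "probability": prob,
            "average_sets": labels, "difference_sets": labels}


def greedy_search_and_average(model: GroupModel,
                              candidates: list[int] | None = None,
                              max_models: int = 2 ** 16) -> dict:
    """Greedy pruning of second-level coefficients + model averaging.

    Each iteration scores every remaining coefficient's removal; all
    removals that do not reduce the free energy are then pruned as a
    batch (falling back to the single best removal if the batch as a
    whole reduces F; ties broken by first index).  The search stops when
    no removal avoids reducing F.  The returned average is weighted by
    softmax evidence over the models evaluated in the final sweep.
    """
    KM = len(model.beta.names)
    if candidates is None:
        candidates = list(range(KM))
    off: list[int] = []
    evaluated = 0
    current_F = 0.0  # relative to the full model
    last_sweep: list[tuple[float, list[int]]] = [(0.0, [])]
    while evaluated < max_models:
        remaining = [i for i in candidates if i not in off]
        sweep = []
        for i in remaining:
            if evaluated >= max_models:
                break
            dF, _ = bayesian_model_reduction(
                model, _reduced_prior_switch_off(model, off + [i]))
            evaluated += 1
            sweep.append((dF, off + [i]))
        if not sweep:
            break
        last_sweep = sweep + [(current_F, list(off))]
        improving = [(dF, o) for dF, o in sweep if dF >= current_F]
        if not improving:
            break
        batch = sorted({o[-1] for _, o in improving})
        if len(batch) > 1:
            dF_batch, _ = bayesian_model_reduction(
                model, _reduced_prior_switch_off(model, off + batch))
            evaluated += 1
            if dF_batch >= current_F:
                off = off + batch
                current_F = dF_batch
                continue
        best_dF, best_off = max(improving, key=lambda t: (t[0], -t[1][-1]))
        off = best_off
        current_F = best_dF

    # evidence-weighted average over the final candidate set
    entries = []
    for dF, off_i in last_sweep:
        _, post = bayesian_model_reduction(
            model, _reduced_prior_switch_off(model, off_i))
        entries.append((dF, post))
    w = softmax(np.array([e[0] for e in entries]))
    mean = sum(wi * e[1].mean for wi, e in zip(w, entries))
    cov = sum(wi * (e[1].cov + np.outer(e[1].mean, e[1].mean))
              for wi, e in zip(w, entries)) - np.outer(mean, mean)
    bma = GaussianDensity(list(model.beta.names), mean, 0.5 * (cov + cov.T))
    return {"pruned": sorted(off), "free_energy_gain": current_F,
            "weights": w.tolist(), "average": bma,
            "models_evaluated": evaluated}


def parameter_probability(model: GroupModel, index: int) -> float:
    """Posterior probability that one coefficient is present.

    Softmax over the free energies of the model with the coefficient on
    versus switched off (all other coefficients untouched).
    """
    if not 0 <= index < len(model.beta.names):
        raise IndexError("coefficient index out of range")
    dF_off, _ = bayesian_model_reduction(
        model, _reduced_prior_switch_off(model, [index]))
    # F_on = 0 (full model reference)
    return float(softmax(np.array([0.0, dF_off]))[0])
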