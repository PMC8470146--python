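"""Per-subject Bayesian inversion of the generative model.

Two candidate architectures are expressed purely through priors:

* ``m1`` (left driving): condition inputs may enter lSMA and lPMd;
* ``m2`` (right driving): condition inputs may enter rSMA and rPMd.

All between-region connections are switched on in both variants.
Switching a parameter "off" means giving it zero prior variance, which
fixes it at its prior mean (zero).  The inversion optimises a
variational free energy (accuracy minus complexity), which is also the
model-evidence approximation used for Bayesian model comparison.

The estimator follows scikit-learn conventions: ``fit(X, y)`` with
``X`` the microtime input matrix and ``y`` the scan-by-region data
table; fitted attributes carry a trailing underscore.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import softmax
from sklearn.base import BaseEstimator

from .design import InputMatrix
from .gaussian import GaussianDensity
from .integrate import integrate_forward
from .model import SubjectModel, ObservationConstants
from .vl import InversionSettings, variational_laplace_engine, ConvergenceError

__all__ = [
    "PRIOR_VARIANCES",
    "default_priors",
    "DCMForward",
    "DCMInverter",
    "variational_laplace",
    "reestimate_from_start",
    "explained_variance",
    "compare_evidence",
]

#: default prior variances per parameter field (configurable)
PRIOR_VARIANCES = {
    "A": 1.0 / 16.0,        # between-region connections, Hz
    "selfA": 1.0 / 16.0,    # self-connection log-scalers
    "C": 1.0,               # driving inputs (where switched on), Hz
    "decay": 1.0 / 256.0,   # vasoactive decay log-scaler
    "transit": 1.0 / 256.0,  # transit-time log-scalers
    "offset": 1.0,          # per-region constant offsets (observation)
}

DRIVING_REGIONS = {"m1": ("lSMA", "lPMd"), "m2": ("rSMA", "rPMd")}


def default_priors(
    variant: str = "m1",
    regions: tuple[str, ...] = SubjectModel.zeros().regions,
    conditions: tuple[str, ...] = SubjectModel.zeros().conditions,
    prior_variances: dict[str, float] | None = None,
) -> GaussianDensity:
    """Zero-mean priors with variance-based model switching.

    All A parameters (between-region and self) are switched on; driving
    inputs are switched on only for the variant's driving regions; the
    haemodynamic log-scalers and per-region offsets are always on.
    """
    if variant not in DRIVING_REGIONS:
        raise ValueError(f"unknown model variant {variant!r}; use 'm1' or 'm2'")
    pv = dict(PRIOR_VARIANCES)
    if prior_variances:
        pv.update(prior_variances)
    driving = DRIVING_REGIONS[variant]
    names, variances = [], []
    for src in regions:
        for dst in regions:
            if src != dst:
                names.append(f"A_{src}->{dst}")
                variances.append(pv["A"])
    for r in regions:
        names.append(f"selfA_{r}")
        variances.append(pv["selfA"])
    for r in regions:
        for c in conditions:
            names.append(f"C_{r}_{c}")
            variances.append(pv["C"] if r in driving else 0.0)
    names.append("decay")
    variances.append(pv["decay"])
    for r in regions:
        names.append(f"transit_{r}")
        variances.append(pv["transit"])
    for r in regions:
        names.append(f"offset_{r}")
        variances.append(pv["offset"])
    return GaussianDensity.diagonal(names, np.zeros(len(names)), variances)


class DCMForward:
    """Maps a named parameter vector to a flattened BOLD prediction.

    The prediction is the forward-integrated BOLD per scan plus a
    per-region constant offset, flattened region-major so each region's
    samples are contiguous (matching the per-region noise groups).
    """

    def __init__(self, inputs: InputMatrix, names: list[str],
                 constants: ObservationConstants | None = None,
                 regions: tuple[str, ...] = SubjectModel.zeros().regions,
                 conditions: tuple[str, ...] = SubjectModel.zeros().conditions,
                 method: str = "rk4"):
        self.inputs = inputs
        self.names = list(names)
        self.regions = regions
        self.conditions = conditions
        self.constants = constants or ObservationConstants()
        self.method = method
        self._offset_idx = {n: i for i, n in enumerate(self.names)
                            if n.startswith("offset_")}
        self._model_names = [n for n in self.names if not n.startswith("offset_")]

    @property
    def n_obs(self) -> int:
        return self.inputs.n_scans * len(self.regions)

    def group_slices(self) -> list[slice]:
        V = self.inputs.n_scans
        return [slice(r * V, (r + 1) * V) for r in range(len(self.regions))]

    def model_from(self, theta: np.ndarray) -> SubjectModel:
        m = SubjectModel.zeros(self.regions, self.conditions, self.constants)
        for name, value in zip(self.names, theta):
            if not name.startswith("offset_"):
                m.set_parameter(name, float(value))
        return m

    def offsets_from(self, theta: np.ndarray) -> np.ndarray:
        out = np.zeros(len(self.regions))
        for i, r in enumerate(self.regions):
            key = f"offset_{r}"
            if key in self._offset_idx:
                out[i] = theta[self._offset_idx[key]]
        return out

    def predict(self, theta: np.ndarray) -> np.ndarray:
        """(V, R) prediction table at a parameter vector."""
        m = self.model_from(theta)
        pred = integrate_forward(m, self.inputs, method=self.method).to_numpy()
        return pred + self.offsets_from(theta)[None, :]

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        return self.predict(theta).T.ravel()  # region-major flattening


def _flatten_data(data, regions) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        data = data[list(regions)].to_numpy()
    data = np.asarray(data, dtype=float)
    return data.T.ravel()


class DCMInverter(BaseEstimator):
    """Variational Laplace inversion of one subject's generative model.

    Parameters
    ----------
    variant : {"m1", "m2"}
        Which driving-input architecture the priors express.
    priors : GaussianDensity, optional
        Overrides the variant's default priors.
    settings : InversionSettings, optional
    constants : ObservationConstants, optional
    reestimate_from : array or GaussianDensity, optional
        Additional start value (e.g., group-average connectivity); the
        returned fit is whichever start achieved the higher free energy.

    Attributes
    ----------
    posterior_ : GaussianDensity (with free energy)
    free_energy_ : float
    explained_variance_ : dict region -> percent
    model_ : SubjectModel at the posterior mean
    """

    def __init__(self, variant: str = "m1", priors: GaussianDensity | None = None,
                 settings: InversionSettings | None = None,
                 constants: ObservationConstants | None = None,
                 reestimate_from=None, method: str = "rk4"):
        self.variant = variant
        self.priors = priors
        self.settings = settings
        self.constants = constants
        self.reestimate_from = reestimate_from
        self.method = method

    def _build(self, X: InputMatrix):
        priors = self.priors if self.priors is not None else default_priors(self.variant)
        forward = DCMForward(X, priors.names, constants=self.constants,
                             method=self.method)
        return priors, forward

    def fit(self, X: InputMatrix, y) -> "DCMInverter":
        priors, forward = self._build(X)
        y_flat = _flatten_data(y, forward.regions)
        if y_flat.size != forward.n_obs:
            raise ValueError(
                f"data size {y_flat.size} != expected {forward.n_obs}")
        settings = self.settings or InversionSettings()
        post = variational_laplace_engine(
            forward, y_flat, priors, group_slices=forward.group_slices(),
            settings=settings)
        if self.reestimate_from is not None:
            start = self.reestimate_from
            if isinstance(start, GaussianDensity):
                start = _align_start(start, priors)
            alt = variational_laplace_engine(
                forward, y_flat, priors, group_slices=forward.group_slices(),
                settings=settings, start_mean=np.asarray(start, dtype=float))
            if alt.free_energy > post.free_energy:
                alt.meta["restarted"] = True
                post = alt
        self.posterior_ = post
        self.free_energy_ = float(post.free_energy)
        self.forward_ = forward
        self.prediction_ = pd.DataFrame(forward.predict(post.mean),
                                        columns=list(forward.regions))
        self.model_ = forward.model_from(post.mean)
        self.explained_variance_ = explained_variance(post, forward, y)
        return self

    def predict(self, X: InputMatrix | None = None) -> pd.DataFrame:
        if X is None:
            return self.prediction_
        priors = self.posterior_
        forward = DCMForward(X, priors.names, constants=self.constants,
                             method=self.method)
        return pd.DataFrame(forward.predict(priors.mean),
                            columns=list(forward.regions))


def _align_start(density: GaussianDensity, priors: GaussianDensity) -> np.ndarray:
    """Start vector aligned with the prior; absent names start at prior mean."""
    start = priors.mean.copy()
    for i, n in enumerate(priors.names):
        if n in density.names:
            start[i] = density.mean[density.index(n)]
    return start


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def variational_laplace(data, inputs: InputMatrix, priors: GaussianDensity,
                        settings: InversionSettings | None = None,
                        constants: ObservationConstants | None = None) -> GaussianDensity:
    """Fit one subject; returns the Gaussian posterior with free energy."""
    inv = DCMInverter(priors=priors, settings=settings, constants=constants)
    inv.fit(inputs, data)
    return inv.posterior_


def reestimate_from_start(data, inputs: InputMatrix, priors: GaussianDensity,
                          start_mean, settings: InversionSettings | None = None,
                          constants: ObservationConstants | None = None) -> GaussianDensity:
    """Fit from the default start and from ``start_mean``; keep the higher-F fit."""
    inv = DCMInverter(priors=priors, settings=settings, constants=constants,
                      reestimate_from=start_mean)
    inv.fit(inputs, data)
    return inv.posterior_


def explained_variance(posterior: GaussianDensity, model_context: DCMForward,
                       data) -> dict[str, float]:
    """Percent variance explained per region by the posterior-mean prediction.

    ``100 * (1 - RSS/TSS)``; negative when the model fits worse than the
    region mean; NaN (reported missing) for zero-variance data columns.
    """
    if isinstance(data, pd.DataFrame):
        data = data[list(model_context.regions)].to_numpy()
    data = np.asarray(data, dtype=float)
    pred = model_context.predict(posterior.mean)
    out: dict[str, float] = {}
    for j, region in enumerate(model_context.regions):
        tss = float(np.sum((data[:, j] - data[:, j].mean()) ** 2))
        if tss == 0.0:
            out[region] = float("nan")
            continue
        rss = float(np.sum((data[:, j] - pred[:, j]) ** 2))
        out[region] = 100.0 * (1.0 - rss / tss)
    return out


def compare_evidence(free_energies) -> dict:
    """Log Bayes factors and posterior model probabilities.

    Probabilities are the softmax of the free energies under uniform
    model priors (invariant to adding a constant to every F).
    """
    F = np.asarray(list(free_energies), dtype=float)
    if F.size < 2:
        raise ValueError("need at least two models to compare")
    if not np.all(np.isfinite(F)):
        raise ValueError("free energies must be finite")
    log_bf = F[:, None] - F[None, :]
    return {
        "free_energies": F.tolist(),
        "log_bayes_factors": log_bf.tolist(),
        "probabilities": softmax(F).tolist(),
    }
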