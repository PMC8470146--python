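"""The generative model: linear neural dynamics + balloon haemodynamics.

Six motor regions (lM1, lPMd, lSMA, rM1, rPMd, rSMA by default) carry a
scalar neural state each, coupled by an effective-connectivity matrix A
(Hz) and driven by condition indicators through matrix C (Hz).  Each
region's neural activity feeds a vasoactive signal that drives blood
inflow, venous volume and deoxyhaemoglobin (the balloon model), and a
static observation equation turns volume and deoxyhaemoglobin into a
fractional BOLD signal change, using constants appropriate for 3 T.

Orientation convention
----------------------
``A[i, j]`` is the rate of change of activity in region *j* per unit
activity in region *i* — rows index **sources**, columns index targets.
This is the reverse of the common ODE convention; the neural derivative
therefore uses ``A.T @ z``.

Self-connections are never stored directly: the diagonal of the
effective matrix is ``-0.5 * exp(lambda_A[j])`` Hz, negative for every
finite value of the unitless log-scaler ``lambda_A[j]``.  Likewise the
vasoactive decay rate is ``0.64 * exp(lambda_kappa)`` Hz (one scaler
pooled over regions) and the venous transit time is
``2 * exp(lambda_tau[j])`` s per region.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .design import CONDITIONS

__all__ = [
    "REGIONS",
    "ObservationConstants",
    "SubjectModel",
    "self_connection_strength",
    "decay_rate",
    "transit_time",
    "neural_derivative",
    "haemodynamic_derivative",
    "bold_observation",
    "bold_coefficients",
    "nu0_from_field_strength",
    "epsilon_prior_fit",
]

REGIONS: tuple[str, ...] = ("lM1", "lPMd", "lSMA", "rM1", "rPMd", "rSMA")

#: default self-inhibition strength, Hz (Eq. 2 scaling constant)
SELF_INHIBITION_HZ = -0.5
#: default vasoactive-signal decay rate, Hz
DECAY_HZ = 0.64
#: default venous transit time, s
TRANSIT_S = 2.0


def nu0_from_field_strength(b0_tesla: float) -> float:
    """Frequency offset at the outer surface of magnetised vessels (Hz).

    Linear in the main magnetic field strength: ``nu0 = 28.265 * B0``.
    """
    if b0_tesla <= 0:
        raise ValueError("field strength must be positive")
    return 28.265 * b0_tesla


@dataclass(frozen=True)
class ObservationConstants:
    """Fixed constants of the BOLD observation and balloon equations.

    Defaults are the 3 T values used throughout this package: echo time
    0.03 s, resting venous volume fraction 4%, intravascular relaxation
    slope 110 Hz, vessel-surface frequency offset 84.8 Hz, and the
    intra/extra-vascular signal ratio epsilon fixed at 0.46.  E0, gamma
    and alpha are standard balloon-model constants.
    """

    epsilon: float = 0.46        # intra/extra-vascular signal ratio
    V0: float = 0.04             # resting venous volume fraction
    r0: float = 110.0            # Hz, intravascular relaxation slope
    nu0: float = 84.8            # Hz, vessel-surface frequency offset
    TE: float = 0.03             # s, echo time
    E0: float = 0.4              # resting oxygen extraction fraction
    gamma: float = 0.32          # Hz, flow-feedback rate
    alpha: float = 0.32          # Grubb exponent
    B0: float = 3.0              # Tesla

    def __post_init__(self) -> None:
        for name in ("epsilon", "V0", "r0", "nu0", "TE", "E0", "gamma", "alpha", "B0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("V0", "E0", "alpha"):
            if getattr(self, name) >= 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    @staticmethod
    def from_field_strength(b0_tesla: float, **kwargs) -> "ObservationConstants":
        return ObservationConstants(nu0=nu0_from_field_strength(b0_tesla),
                                    B0=b0_tesla, **kwargs)


def bold_coefficients(constants: ObservationConstants) -> tuple[float, float, float]:
    """Coefficients (k1, k2, k3) of the BOLD observation equation."""
    c = constants
    k1 = 4.3 * c.nu0 * c.E0 * c.TE
    k2 = c.epsilon * c.r0 * c.E0 * c.TE
    k3 = 1.0 - c.epsilon
    return k1, k2, k3


@dataclass
class SubjectModel:
    """All free parameters of one subject's generative model.

    Attributes
    ----------
    A : (R, R) ndarray, Hz
        Between-region effective connectivity; the diagonal is ignored
        (kept at zero) — self-connections come from ``lambda_A``.
    lambda_A : (R,) ndarray
        Unitless log-scalers of the −0.5 Hz self-inhibition.
    C : (R, P) ndarray, Hz
        Driving-input strength of each condition on each region.
    lambda_kappa : float
        Log-scaler of the 0.64 Hz vasoactive decay rate (pooled).
    lambda_tau : (R,) ndarray
        Per-region log-scalers of the 2 s venous transit time.
    """

    A: np.ndarray
    lambda_A: np.ndarray
    C: np.ndarray
    lambda_kappa: float = 0.0
    lambda_tau: np.ndarray | None = None
    constants: ObservationConstants = field(default_factory=ObservationConstants)
    regions: tuple[str, ...] = REGIONS
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        R, P = len(self.regions), len(self.conditions)
        self.A = np.array(self.A, dtype=float)
        self.C = np.array(self.C, dtype=float)
        self.lambda_A = np.array(self.lambda_A, dtype=float).ravel()
        if self.lambda_tau is None:
            self.lambda_tau = np.zeros(R)
        self.lambda_tau = np.array(self.lambda_tau, dtype=float).ravel()
        if self.A.shape != (R, R):
            raise ValueError(f"A must be ({R},{R}), got {self.A.shape}")
        if self.C.shape != (R, P):
            raise ValueError(f"C must be ({R},{P}), got {self.C.shape}")
        if self.lambda_A.shape != (R,) or self.lambda_tau.shape != (R,):
            raise ValueError("lambda_A and lambda_tau must have one entry per region")
        np.fill_diagonal(self.A, 0.0)

    # -- derived quantities ---------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def full_A(self) -> np.ndarray:
        """Connectivity with parameterised self-connections on the diagonal."""
        A = self.A.copy()
        np.fill_diagonal(A, self_connection_strength(self.lambda_A))
        return A

    @property
    def kappa(self) -> float:
        return decay_rate(self.lambda_kappa)

    @property
    def tau(self) -> np.ndarray:
        return transit_time(self.lambda_tau)

    @staticmethod
    def zeros(regions: tuple[str, ...] = REGIONS,
              conditions: tuple[str, ...] = CONDITIONS,
              constants: ObservationConstants | None = None) -> "SubjectModel":
        R, P = len(regions), len(conditions)
        return SubjectModel(
            A=np.zeros((R, R)), lambda_A=np.zeros(R), C=np.zeros((R, P)),
            lambda_kappa=0.0, lambda_tau=np.zeros(R),
            constants=constants or ObservationConstants(),
            regions=regions, conditions=conditions)

    def copy(self) -> "SubjectModel":
        return replace(self, A=self.A.copy(), lambda_A=self.lambda_A.copy(),
                       C=self.C.copy(), lambda_tau=self.lambda_tau.copy())

    # -- named-parameter access (used by inversion and perturbation) ----
    def parameter_names(self, include_self: bool = True,
                        include_haemo: bool = True) -> list[str]:
        names = [f"A_{src}->{dst}" for src in self.regions for dst in self.regions
                 if src != dst]
        if include_self:
            names += [f"selfA_{r}" for r in self.regions]
        names += [f"C_{r}_{c}" for r in self.regions for c in self.conditions]
        if include_haemo:
            names += ["decay"] + [f"transit_{r}" for r in self.regions]
        return names

    def _region(self, label: str) -> int:
        if label not in self.regions:
            raise KeyError(f"unknown region {label!r}")
        return self.regions.index(label)

    def _condition(self, label: str) -> int:
        if label not in self.conditions:
            raise KeyError(f"unknown condition {label!r}")
        return self.conditions.index(label)

    def get_parameter(self, name: str) -> float:
        if name == "decay":
            return float(self.lambda_kappa)
        kind, _, rest = name.partition("_")
        if kind == "A" and "->" in rest:
            src, dst = rest.split("->")
            return float(self.A[self._region(src), self._region(dst)])
        if kind == "selfA":
            return float(self.lambda_A[self._region(rest)])
        if kind == "C" and "_" in rest:
            r, c = rest.rsplit("_", 1)
            return float(self.C[self._region(r), self._condition(c)])
        if kind == "transit":
            return float(self.lambda_tau[self._region(rest)])
        raise KeyError(f"unknown parameter {name!r}")

    def set_parameter(self, name: str, value: float) -> None:
        kind, _, rest = name.partition("_")
        if kind == "A" and "->" in rest:
            src, dst = rest.split("->")
            i, j = self._region(src), self._region(dst)
            if i == j:
                raise KeyError("self-connections are set through selfA_<region>")
            self.A[i, j] = value
        elif kind == "selfA":
            self.lambda_A[self._region(rest)] = value
        elif kind == "C" and "_" in rest:
            r, c = rest.rsplit("_", 1)
            self.C[self._region(r), self._condition(c)] = value
        elif name == "decay":
            self.lambda_kappa = float(value)
        elif kind == "transit":
            self.lambda_tau[self._region(rest)] = value
        else:
            raise KeyError(f"unknown parameter {name!r}")

    def to_dict(self) -> dict:
        return {
            "regions": list(self.regions),
            "conditions": list(self.conditions),
            "A": self.A.tolist(),
            "lambda_A": self.lambda_A.tolist(),
            "C": self.C.tolist(),
            "lambda_kappa": float(self.lambda_kappa),
            "lambda_tau": self.lambda_tau.tolist(),
            "constants": {k: float(getattr(self.constants, k))
                          for k in ("epsilon", "V0", "r0", "nu0", "TE",
                                    "E0", "gamma", "alpha", "B0")},
        }

    @staticmethod
    def from_dict(d: dict) -> "SubjectModel":
        return SubjectModel(
            A=np.asarray(d["A"], dtype=float),
            lambda_A=np.asarray(d["lambda_A"], dtype=float),
            C=np.asarray(d["C"], dtype=float),
            lambda_kappa=float(d["lambda_kappa"]),
            lambda_tau=np.asarray(d["lambda_tau"], dtype=float),
            constants=ObservationConstants(**d["constants"]),
            regions=tuple(d["regions"]),
            conditions=tuple(d["conditions"]),
        )


# ---------------------------------------------------------------------------
# parameterisations
# ---------------------------------------------------------------------------

def self_connection_strength(lam):
    """Effective self-connection, Hz: ``-0.5 * exp(lam)`` — always negative."""
    lam = np.asarray(lam, dtype=float)
    if not np.all(np.isfinite(lam)):
        raise ValueError("self-connection log-scaler must be finite")
    out = SELF_INHIBITION_HZ * np.exp(lam)
    return float(out) if out.ndim == 0 else out


def decay_rate(lambda_kappa: float) -> float:
    """Vasoactive-signal decay rate, Hz: ``0.64 * exp(lambda_kappa)``."""
    if not np.isfinite(lambda_kappa):
        raise ValueError("decay log-scaler must be finite")
    return DECAY_HZ * float(np.exp(lambda_kappa))


def transit_time(lambda_tau):
    """Venous transit time, s: ``2 * exp(lambda_tau)`` per region."""
    lam = np.asarray(lambda_tau, dtype=float)
    if not np.all(np.isfinite(lam)):
        raise ValueError("transit log-scaler must be finite")
    out = TRANSIT_S * np.exp(lam)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# derivatives and observation
# ---------------------------------------------------------------------------

def neural_derivative(z: np.ndarray, u: np.ndarray, model: SubjectModel) -> np.ndarray:
    """Rate of change of neural activity: ``dz/dt = A_full' z + C u``.

    The transpose follows the row-source orientation of ``A``.
    """
    z = np.asarray(z, dtype=float).ravel()
    u = np.asarray(u, dtype=float).ravel()
    if z.shape != (model.n_regions,) or u.shape != (model.n_conditions,):
        raise ValueError("state/input dimensions do not match the model")
    return model.full_A().T @ z + model.C @ u


def haemodynamic_derivative(z, s, f, v, q, model: SubjectModel):
    """Balloon-model state derivatives (per region).

    ``ds = z - kappa*s - gamma*(f-1)``; ``df = s``;
    ``tau*dv = f - v**(1/alpha)``;
    ``tau*dq = f*(1-(1-E0)**(1/f))/E0 - v**(1/alpha) * q/v``.
    """
    z, s, f, v, q = (np.asarray(x, dtype=float).ravel() for x in (z, s, f, v, q))
    if np.any(f <= 0) or np.any(v <= 0) or np.any(q <= 0):
        raise ValueError("flow, volume and deoxyhaemoglobin must stay positive")
    c = model.constants
    kappa = model.kappa
    tau = model.tau
    ds = z - kappa * s - c.gamma * (f - 1.0)
    df = s
    outflow = v ** (1.0 / c.alpha)
    dv = (f - outflow) / tau
    extraction = (1.0 - (1.0 - c.E0) ** (1.0 / f)) / c.E0
    dq = (f * extraction - outflow * q / v) / tau
    return ds, df, dv, dq


def bold_observation(v, q, constants: ObservationConstants):
    """Fractional BOLD signal change from venous volume and dHb.

    ``y = V0 * (k1*(1-q) + k2*(1-q/v) + k3*(1-v))``; zero at rest
    (v = q = 1).
    """
    v = np.asarray(v, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(v <= 0) or np.any(q <= 0):
        raise ValueError("volume and deoxyhaemoglobin must be positive")
    k1, k2, k3 = bold_coefficients(constants)
    y = constants.V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
    return float(y) if y.ndim == 0 else y


# ---------------------------------------------------------------------------
# epsilon prior derivation
# ---------------------------------------------------------------------------

def epsilon_prior_fit(
    T2i_range_ms: tuple[float, float] = (15.0, 25.0),
    T2e_range_ms: tuple[float, float] = (30.0, 45.0),
    step_ms: float = 0.5,
    TE_ms: float = 30.0,
    criterion: str = "mle_log",
) -> tuple[float, float]:
    """Lognormal density over the intra/extra-vascular signal ratio.

    Evaluates ``epsilon = exp(-TE/T2i*) / exp(-TE/T2e*)`` on a grid of
    intravascular and extravascular relaxation times and fits a
    lognormal to the resulting values.

    Parameters
    ----------
    criterion : {"mle_log", "moment"}
        "mle_log" fits by maximum likelihood on log-values (Gaussian
        mean/variance of ``log epsilon``); "moment" matches the mean and
        variance of log-values computed with the unbiased variance.

    Returns
    -------
    (location, scale_sq) : tuple of float
        Parameters of ``Lognormal(location, scale_sq)``, i.e., mean and
        variance of ``log epsilon``.
    """
    for lo, hi in (T2i_range_ms, T2e_range_ms):
        if lo <= 0 or hi < lo:
            raise ValueError("relaxation-time ranges must be positive with min <= max")
    if step_ms <= 0:
        raise ValueError("step must be positive")
    t2i = np.arange(T2i_range_ms[0], T2i_range_ms[1] + step_ms / 2, step_ms)
    t2e = np.arange(T2e_range_ms[0], T2e_range_ms[1] + step_ms / 2, step_ms)
    if t2i.size == 0 or t2e.size == 0:
        raise ValueError("empty relaxation-time grid")
    I, E = np.meshgrid(t2i, t2e, indexing="ij")
    log_eps = (TE_ms / E - TE_ms / I).ravel()
    if criterion == "mle_log":
        loc = float(np.mean(log_eps))
        scale_sq = float(np.var(log_eps))
    elif criterion == "moment":
        loc = float(np.mean(log_eps))
        scale_sq = float(np.var(log_eps, ddof=1))
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return loc, scale_sq


def epsilon_prior_density(loc: float, scale_sq: float):
    """scipy frozen lognormal with the given log-mean and log-variance."""
    return stats.lognorm(s=np.sqrt(scale_sq), scale=np.exp(loc))
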