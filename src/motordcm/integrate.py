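"""Numerical integration of the coupled neural/haemodynamic system.

The state per region is (z, s, f, v, q): neural activity, vasoactive
signal, normalised inflow, venous volume and deoxyhaemoglobin.  From
rest (z = s = 0, f = v = q = 1) with zero input the system stays at rest
and the BOLD output is identically zero.

Integration is fixed-step on the microtime grid of the input matrix
(one step per bin, inputs held constant within a bin), fourth-order
Runge-Kutta by default with a first-order explicit mode available.  The
hot loop is numba-compiled; a pure-Python reference path is kept for
cross-validation.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit

from .design import InputMatrix
from .model import SubjectModel, bold_coefficients

__all__ = ["InstabilityError", "integrate_forward", "volterra_kernel"]

#: state-norm bound beyond which integration is declared unstable
STATE_NORM_BOUND = 1e6


class InstabilityError(RuntimeError):
    """Raised when the state diverges during forward integration."""


@njit(cache=False)
def _deriv(state, u, AT, C, kappa, gamma, tau, alpha, E0):
    R = AT.shape[0]
    z = state[0:R]
    s = state[R:2 * R]
    f = state[2 * R:3 * R]
    v = state[3 * R:4 * R]
    q = state[4 * R:5 * R]
    d = np.empty(5 * R)
    d[0:R] = AT @ z + C @ u
    d[R:2 * R] = z - kappa * s - gamma * (f - 1.0)
    d[2 * R:3 * R] = s
    for j in range(R):
        outflow = v[j] ** (1.0 / alpha)
        d[3 * R + j] = (f[j] - outflow) / tau[j]
        extraction = (1.0 - (1.0 - E0) ** (1.0 / f[j])) / E0
        d[4 * R + j] = (f[j] * extraction - outflow * q[j] / v[j]) / tau[j]
    return d


@njit(cache=False)
def _integrate_core(AT, C, U, dt, kappa, gamma, tau, alpha, E0,
                    V0, k1, k2, k3, bins_per_scan, sample_offset, rk4):
    T = U.shape[0]
    R = AT.shape[0]
    n_scans = T // bins_per_scan
    state = np.zeros(5 * R)
    state[2 * R:5 * R] = 1.0  # f = v = q = 1 at rest
    Y = np.zeros((n_scans, R))
    status = 0
    for k in range(T):
        # sample BOLD at the configured bin within each scan
        if k % bins_per_scan == sample_offset:
            i = k // bins_per_scan
            v = state[3 * R:4 * R]
            q = state[4 * R:5 * R]
            for j in range(R):
                Y[i, j] = V0 * (k1 * (1.0 - q[j]) + k2 * (1.0 - q[j] / v[j])
                                + k3 * (1.0 - v[j]))
        u = U[k]
        if rk4:
            d1 = _deriv(state, u, AT, C, kappa, gamma, tau, alpha, E0)
            d2 = _deriv(state + 0.5 * dt * d1, u, AT, C, kappa, gamma, tau, alpha, E0)
            d3 = _deriv(state + 0.5 * dt * d2, u, AT, C, kappa, gamma, tau, alpha, E0)
            d4 = _deriv(state + dt * d3, u, AT, C, kappa, gamma, tau, alpha, E0)
            state = state + (dt / 6.0) * (d1 + 2.0 * d2 + 2.0 * d3 + d4)
        else:
            state = state + dt * _deriv(state, u, AT, C, kappa, gamma, tau, alpha, E0)
        ok = True
        for j in range(5 * R):
            if not np.isfinite(state[j]) or abs(state[j]) > STATE_NORM_BOUND:
                ok = False
        for j in range(2 * R, 5 * R):
            if state[j] <= 0.0:
                ok = False
        if not ok:
            status = 1
            break
    return Y, status


def _integrate_python(AT, C, U, dt, kappa, gamma, tau, alpha, E0,
                      V0, k1, k2, k3, bins_per_scan, sample_offset, rk4):
    """Pure-numpy mirror of the compiled core (reference path)."""
    T, R = U.shape[0], AT.shape[0]
    n_scans = T // bins_per_scan

    def deriv(state, u):
        z, s = state[0:R], state[R:2 * R]
        f, v, q = state[2 * R:3 * R], state[3 * R:4 * R], state[4 * R:5 * R]
        d = np.empty(5 * R)
        d[0:R] = AT @ z + C @ u
        d[R:2 * R] = z - kappa * s - gamma * (f - 1.0)
        d[2 * R:3 * R] = s
        outflow = v ** (1.0 / alpha)
        d[3 * R:4 * R] = (f - outflow) / tau
        d[4 * R:5 * R] = (f * (1.0 - (1.0 - E0) ** (1.0 / f)) / E0
                          - outflow * q / v) / tau
        return d

    state = np.zeros(5 * R)
    state[2 * R:] = 1.0
    Y = np.zeros((n_scans, R))
    status = 0
    for k in range(T):
        if k % bins_per_scan == sample_offset:
            v, q = state[3 * R:4 * R], state[4 * R:5 * R]
            Y[k // bins_per_scan] = V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v)
                                          + k3 * (1.0 - v))
        u = U[k]
        if rk4:
            d1 = deriv(state, u)
            d2 = deriv(state + 0.5 * dt * d1, u)
            d3 = deriv(state + 0.5 * dt * d2, u)
            d4 = deriv(state + dt * d3, u)
            state = state + (dt / 6.0) * (d1 + 2 * d2 + 2 * d3 + d4)
        else:
            state = state + dt * deriv(state, u)
        if (not np.all(np.isfinite(state)) or np.any(np.abs(state) > STATE_NORM_BOUND)
                or np.any(state[2 * R:] <= 0)):
            status = 1
            break
    return Y, status


def integrate_forward(
    model: SubjectModel,
    inputs: InputMatrix,
    method: str = "rk4",
    sample_offset: int | None = None,
    engine: str = "numba",
) -> pd.DataFrame:
    """Predicted BOLD, one row per scan, one column per region.

    Parameters
    ----------
    method : {"rk4", "euler"}
        Fixed-step integrator order.
    sample_offset : int, optional
        Microtime bin within each scan at which the prediction is
        sampled; defaults to mid-scan (``bins_per_scan // 2``).
    engine : {"numba", "python"}
        Compiled core or the pure-Python reference implementation.

    Raises
    ------
    InstabilityError
        If any hidden state exceeds the configured norm bound or a
        haemodynamic state loses positivity.
    """
    if model.n_conditions != inputs.values.shape[1]:
        raise ValueError(
            f"model has {model.n_conditions} conditions but inputs have "
            f"{inputs.values.shape[1]} columns")
    if method not in ("rk4", "euler"):
        raise ValueError(f"unknown method {method!r}")
    if sample_offset is None:
        sample_offset = inputs.bins_per_scan // 2
    if not 0 <= sample_offset < inputs.bins_per_scan:
        raise ValueError("sample_offset must lie within a scan")
    c = model.constants
    k1, k2, k3 = bold_coefficients(c)
    fn = _integrate_core if engine == "numba" else _integrate_python
    Y, status = fn(
        np.ascontiguousarray(model.full_A().T), np.ascontiguousarray(model.C),
        np.ascontiguousarray(inputs.values), float(inputs.bin_width),
        float(model.kappa), float(c.gamma),
        np.ascontiguousarray(model.tau), float(c.alpha), float(c.E0),
        float(c.V0), float(k1), float(k2), float(k3),
        int(inputs.bins_per_scan), int(sample_offset), method == "rk4")
    if status != 0:
        raise InstabilityError(
            "forward integration diverged (state norm bound "
            f"{STATE_NORM_BOUND:g} exceeded or haemodynamic state lost "
            f"positivity); offending parameters: kappa={model.kappa:.3g}, "
            f"tau={np.array2string(model.tau, precision=3)}, "
            f"max|A|={np.abs(model.full_A()).max():.3g}, "
            f"max|C|={np.abs(model.C).max():.3g}")
    return pd.DataFrame(Y, columns=list(model.regions))


def volterra_kernel(
    model: SubjectModel,
    condition: int | str = 0,
    duration: float = 32.0,
    dt: float = 0.125,
    sample_period: float | None = None,
    magnitude: float = 1.0,
    method: str = "rk4",
) -> pd.DataFrame:
    """First-order Volterra kernel: response to a single unit event.

    Integrates the model from rest with a single impulse of the given
    condition at t = 0 and returns the per-region BOLD response sampled
    every ``sample_period`` seconds (defaults to the microtime step for
    a smooth kernel), indexed by time in seconds.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if isinstance(condition, str):
        condition = model.conditions.index(condition)
    if sample_period is None:
        sample_period = dt
    bins_per_sample = max(1, int(round(sample_period / dt)))
    n_samples = int(np.ceil(duration / (bins_per_sample * dt)))
    T = n_samples * bins_per_sample
    U = np.zeros((T, model.n_conditions))
    U[0, condition] = magnitude
    inputs = InputMatrix.__new__(InputMatrix)  # bypass binary-entry check
    inputs.values = U
    inputs.bins_per_scan = bins_per_sample
    inputs.n_scans = n_samples
    inputs.bin_width = dt
    inputs.conditions = model.conditions
    out = integrate_forward(model, inputs, method=method, sample_offset=0)
    out.index = pd.Index(np.arange(n_samples) * bins_per_sample * dt, name="time_s")
    return out
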