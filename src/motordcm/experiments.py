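"""Virtual perturbation experiments on a fitted or constructed model.

Each experiment varies one parameter of a base model around its value,
predicts the ipsilateral-M1 (rM1) response as a first-order Volterra
kernel, and asks whether the perturbation can flip the response's sign.
The "sign of the rM1 BOLD response" is operationalised as the sign of
the kernel's extremum (largest-magnitude point) over a 32 s window.

Connection and driving-input parameters are swept in Hz; log-scaling
parameters (self-connections, decay, transit) are swept in log units.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .integrate import InstabilityError, volterra_kernel
from .model import SubjectModel

__all__ = ["perturb_and_predict", "peak_metrics", "sign_flip_set",
           "connection_amplitude_regression"]

#: |extremum| below this fractional-signal floor counts as "no response"
SIGN_FLOOR = 1e-6

#: parameters swept in log units rather than Hz
LOG_SCALED_PREFIXES = ("selfA_", "transit_", "decay")


def is_log_scaled(parameter: str) -> bool:
    return parameter == "decay" or parameter.startswith(("selfA_", "transit_"))


def perturb_and_predict(
    base: SubjectModel,
    parameter: str,
    offsets,
    condition: str | int = "AV",
    region: str = "rM1",
    duration: float = 32.0,
) -> pd.DataFrame:
    """Family of rM1 kernels, one per offset of a single parameter.

    Returns a tidy long-format table (parameter, offset, time_s, signal);
    offsets whose integration diverges are recorded with NaN signal
    rather than aborting the sweep.  Offset 0 reproduces the base
    kernel exactly.
    """
    base.get_parameter(parameter)  # raises KeyError for unknown names
    frames = []
    for off in np.atleast_1d(np.asarray(offsets, dtype=float)):
        m = base.copy()
        m.set_parameter(parameter, base.get_parameter(parameter) + float(off))
        try:
            k = volterra_kernel(m, condition, duration=duration)
            sig = k[region].to_numpy()
            times = k.index.to_numpy()
        except InstabilityError:
            times = np.array([0.0])
            sig = np.array([np.nan])
        frames.append(pd.DataFrame({
            "parameter": parameter, "offset": float(off),
            "time_s": times, "signal": sig}))
    return pd.concat(frames, ignore_index=True)


def peak_metrics(kernel) -> dict[str, float]:
    """Signed extremum and its latency, plus the half-second rounding.

    The extremum is the largest-|value| sample (ties broken toward the
    earlier time); latency is rounded half-up to the nearest 0.5 s.
    An all-zero kernel has no defined peak: returns NaNs.
    """
    if isinstance(kernel, pd.DataFrame):
        if kernel.shape[1] != 1:
            raise ValueError("pass a single-region kernel")
        kernel = kernel.iloc[:, 0]
    if isinstance(kernel, pd.Series):
        times = np.asarray(kernel.index, dtype=float)
        values = kernel.to_numpy(dtype=float)
    else:
        values = np.asarray(kernel, dtype=float)
        times = np.arange(values.size, dtype=float)
    if values.size == 0:
        raise ValueError("empty kernel")
    if np.all(values == 0.0):
        return {"amplitude": float("nan"), "latency_s": float("nan"),
                "latency_rounded_s": float("nan")}
    i = int(np.argmax(np.abs(values)))  # argmax takes the first maximum
    latency = float(times[i])
    return {"amplitude": float(values[i]), "latency_s": latency,
            "latency_rounded_s": float(np.floor(latency * 2.0 + 0.5) / 2.0)}


@dataclass
class SignFlip:
    parameter: str
    flips: bool
    flip_offset: float | None  # smallest-|offset| sign change, if any
    base_sign: float
    unstable_offsets: list[float]


def _kernel_extremum(model: SubjectModel, condition, region, duration) -> float:
    k = volterra_kernel(model, condition, duration=duration)
    v = k[region].to_numpy()
    return float(v[np.argmax(np.abs(v))])


def sign_flip_set(
    base: SubjectModel,
    parameters=None,
    sweep_range: float = 1.0,
    n_offsets: int = 21,
    condition: str | int = "AV",
    region: str = "rM1",
    duration: float = 32.0,
    bisect_tol: float = 0.01,
) -> list[SignFlip]:
    """Which parameters can flip the sign of the rM1 response?

    Sweeps each parameter over ``n_offsets`` evenly spaced offsets in
    ``[-sweep_range, +sweep_range]`` (Hz for connections and inputs,
    log units for log-scalers); a parameter is in the flip set iff its
    sweep produces extrema of both signs.  The flip offset is refined by
    bisection to ``bisect_tol``.
    """
    base_ext = _kernel_extremum(base, condition, region, duration)
    if abs(base_ext) < SIGN_FLOOR:
        raise ValueError(
            "base model has no well-defined rM1 response sign "
            f"(|extremum| = {abs(base_ext):.2e} below floor {SIGN_FLOOR:g})")
    base_sign = np.sign(base_ext)
    if parameters is None:
        parameters = [n for n in base.parameter_names()]
    offsets = np.linspace(-sweep_range, sweep_range, n_offsets)

    results: list[SignFlip] = []
    for name in parameters:
        signs = {}
        unstable = []
        for off in offsets:
            m = base.copy()
            m.set_parameter(name, base.get_parameter(name) + float(off))
            try:
                ext = _kernel_extremum(m, condition, region, duration)
            except InstabilityError:
                unstable.append(float(off))
                continue
            if abs(ext) >= SIGN_FLOOR:
                signs[float(off)] = np.sign(ext)
        flips = base_sign in signs.values() and -base_sign in signs.values()
        flip_offset = None
        if flips:
            # bracket: adjacent grid offsets with opposite signs, nearest 0
            offs = sorted(signs)
            brackets = [(a, b) for a, b in zip(offs, offs[1:])
                        if signs[a] != signs[b]]
            a, b = min(brackets, key=lambda ab: min(abs(ab[0]), abs(ab[1])))
            sign_a = signs[a]
            while b - a > bisect_tol:
                mid = 0.5 * (a + b)
                m = base.copy()
                m.set_parameter(name, base.get_parameter(name) + mid)
                try:
                    s = np.sign(_kernel_extremum(m, condition, region, duration))
                except InstabilityError:
                    break
                if s == sign_a:
                    a = mid
                else:
                    b = mid
            flip_offset = 0.5 * (a + b)
        results.append(SignFlip(name, flips, flip_offset, float(base_sign),
                                unstable))
    return results


def flipping_parameters(results: list[SignFlip]) -> list[str]:
    return [r.parameter for r in results if r.flips]


def connection_amplitude_regression(
    estimates: pd.DataFrame | dict,
    amplitudes,
) -> dict:
    """How much rM1 response variance do connection estimates explain?

    Ordinary least squares of per-subject rM1 amplitudes on each
    connection separately (reporting Pearson R and R^2) and on all
    connections jointly (reporting the multiple R and R^2).
    """
    if isinstance(estimates, dict):
        estimates = pd.DataFrame(estimates)
    amplitudes = np.asarray(amplitudes, dtype=float)
    n = amplitudes.size
    if len(estimates) != n:
        raise ValueError("estimates and amplitudes must have equal lengths")
    if n < 3:
        raise ValueError("need at least 3 subjects")
    single = {}
    for col in estimates.columns:
        x = estimates[col].to_numpy(dtype=float)
        if np.var(x) == 0:
            single[col] = {"R": float("nan"), "R2": float("nan"),
                           "degenerate": True}
            continue
        fit = sm.OLS(amplitudes, sm.add_constant(x)).fit()
        r = float(np.corrcoef(x, amplitudes)[0, 1])
        single[col] = {"R": r, "R2": float(fit.rsquared), "degenerate": False}
    X = estimates.to_numpy(dtype=float)
    keep = [j for j, c in enumerate(estimates.columns)
            if not single[c].get("degenerate")]
    joint_fit = sm.OLS(amplitudes, sm.add_constant(X[:, keep])).fit()
    return {"single": single,
            "joint_R2": float(joint_fit.rsquared),
            "joint_R": float(np.sqrt(joint_fit.rsquared))}
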