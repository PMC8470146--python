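"""Variational Laplace: Gaussian approximate inference by free-energy ascent.

Generic engine used by the subject-level inversion.  The observation
model is ``y = g(theta) + e`` with independent Gaussian noise whose
precision is grouped (here: one precision per brain region) and
optimised alongside the parameters through log-precision
hyperparameters.  The approximate posterior is a Gaussian whose mean is
updated by damped Gauss-Newton steps on the free energy

    F = accuracy - complexity,

with Levenberg-Marquardt step control: proposals that decrease F are
rejected and the damping increased, so F is non-decreasing over
accepted iterations.  Parameters with exactly zero prior variance are
excluded from the optimisation and returned bit-identical to the prior.

Gradients of the forward model are obtained by central finite
differences; this favours robustness over speed and keeps the engine
agnostic about the forward model's internals.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .gaussian import GaussianDensity

__all__ = ["InversionSettings", "ConvergenceError", "variational_laplace_engine"]

LOG2PI = float(np.log(2.0 * np.pi))


class ConvergenceError(RuntimeError):
    """Raised when the optimisation cannot produce a finite free energy."""


@dataclass
class InversionSettings:
    """Knobs of the variational optimisation.

    ``convergence_tolerance`` is the absolute free-energy change below
    which an accepted iteration counts towards convergence;
    ``converged_after`` such consecutive iterations stop the loop.
    ``fixed_noise_log_precision`` freezes the noise hyperparameters
    (useful for conjugate checks); otherwise they are optimised with a
    Gaussian hyperprior centred on the data's empirical log-precision.
    """

    max_iterations: int = 128
    convergence_tolerance: float = 0.01
    converged_after: int = 4
    fd_step: float = 1e-4
    initial_damping: float = 1e-2
    damping_increase: float = 8.0
    damping_decrease: float = 0.25
    max_rejections: int = 6
    hyper_prior_variance: float = 16.0
    fixed_noise_log_precision: float | np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.convergence_tolerance <= 0:
            raise ValueError("convergence_tolerance must be positive")


def _finite_difference_jacobian(forward: Callable[[np.ndarray], np.ndarray],
                                theta: np.ndarray, free: np.ndarray,
                                step: float, n_obs: int) -> np.ndarray:
    """Central-difference Jacobian over the free parameters only."""
    J = np.zeros((n_obs, int(free.sum())))
    cols = np.flatnonzero(free)
    for c, i in enumerate(cols):
        hi, lo = theta.copy(), theta.copy()
        hi[i] += step
        lo[i] -= step
        try:
            g_hi = forward(hi)
        except Exception:
            g_hi = None
        try:
            g_lo = forward(lo)
        except Exception:
            g_lo = None
        if g_hi is not None and g_lo is not None:
            J[:, c] = (g_hi - g_lo) / (2.0 * step)
        elif g_hi is not None:
            J[:, c] = (g_hi - forward(theta)) / step
        elif g_lo is not None:
            J[:, c] = (forward(theta) - g_lo) / step
        # both sides unstable: leave the column at zero
    return J


def _logdet(M: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(M)
    if sign <= 0:
        raise np.linalg.LinAlgError("matrix not positive definite")
    return float(ld)


def variational_laplace_engine(
    forward: Callable[[np.ndarray], np.ndarray],
    y: np.ndarray,
    prior: GaussianDensity,
    group_slices: Sequence[slice] | None = None,
    settings: InversionSettings | None = None,
    start_mean: np.ndarray | None = None,
) -> GaussianDensity:
    """Fit ``y = forward(theta) + e`` and return the Gaussian posterior.

    Parameters
    ----------
    forward : callable
        Maps a full parameter vector (aligned with ``prior.names``) to a
        flat prediction the same length as ``y``.  May raise on unstable
        parameter values; such proposals are rejected.
    y : (n,) ndarray
        Flattened data.
    prior : GaussianDensity
        Prior over all named parameters; zero-variance entries are fixed.
    group_slices : sequence of slice, optional
        Observation groups sharing a noise precision (default: one group).
    start_mean : ndarray, optional
        Optimisation start value (priors untouched).

    Returns
    -------
    GaussianDensity with ``free_energy`` set; ``meta`` records the
    accepted free-energy trajectory, noise log-precisions and
    convergence diagnostics.
    """
    settings = settings or InversionSettings()
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("data contain non-finite values")
    n = y.size
    if group_slices is None:
        group_slices = [slice(0, n)]
    n_groups = len(group_slices)
    group_sizes = np.array([len(range(*s.indices(n))) for s in group_slices])

    prior_var = prior.variances
    free = prior_var > 0.0
    p = int(free.sum())
    mu0 = prior.mean[free]
    S0 = prior.cov[np.ix_(free, free)]
    Pi0 = np.linalg.inv(S0)
    logdet_S0 = _logdet(S0) if p else 0.0

    theta = prior.mean.copy()
    if start_mean is not None:
        start_mean = np.asarray(start_mean, dtype=float).ravel()
        if start_mean.shape != prior.mean.shape:
            raise ValueError("start_mean must align with the prior")
        theta = prior.mean.copy()
        theta[free] = start_mean[free]

    # noise hyperparameters: log precision per group
    fixed_h = settings.fixed_noise_log_precision
    if fixed_h is not None:
        h = np.broadcast_to(np.asarray(fixed_h, dtype=float), (n_groups,)).copy()
        h0 = h.copy()
    else:
        h0 = np.array([
            -np.log(max(np.var(y[s]), 1e-12)) for s in group_slices])
        h = h0.copy()
    v_h = settings.hyper_prior_variance

    def residual(g: np.ndarray) -> np.ndarray:
        return y - g

    def update_h(e: np.ndarray, J: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Optimise noise log-precisions for fixed mu; returns (h, Sq)."""
        nonlocal h
        if fixed_h is not None:
            iS = np.concatenate([np.full(group_sizes[k], np.exp(h[k]))
                                 for k in range(n_groups)])
            Sq = np.linalg.inv(J.T @ (J * iS[:, None]) + Pi0) if p else np.zeros((0, 0))
            return h, Sq
        for _ in range(8):
            iS = np.concatenate([np.full(group_sizes[k], np.exp(h[k]))
                                 for k in range(n_groups)])
            Sq = np.linalg.inv(J.T @ (J * iS[:, None]) + Pi0) if p else np.zeros((0, 0))
            h_new = h.copy()
            for k, s in enumerate(group_slices):
                Jk = J[s]
                S_k = float(e[s] @ e[s]) + float(np.sum((Jk @ Sq) * Jk)) if p \
                    else float(e[s] @ e[s])
                grad = -0.5 * np.exp(h[k]) * S_k + 0.5 * group_sizes[k] \
                    - (h[k] - h0[k]) / v_h
                curv = -0.5 * np.exp(h[k]) * S_k - 1.0 / v_h
                # clip keeps precisions finite on (near-)noiseless data
                h_new[k] = np.clip(h[k] - grad / curv, -40.0, 40.0)
            if np.max(np.abs(h_new - h)) < 1e-6:
                h = h_new
                break
            h = h_new
        iS = np.concatenate([np.full(group_sizes[k], np.exp(h[k]))
                             for k in range(n_groups)])
        Sq = np.linalg.inv(J.T @ (J * iS[:, None]) + Pi0) if p else np.zeros((0, 0))
        return h, Sq

    def free_energy(e: np.ndarray, Sq: np.ndarray, mu_free: np.ndarray) -> float:
        iS_diag = np.concatenate([np.full(group_sizes[k], np.exp(h[k]))
                                  for k in range(n_groups)])
        F = -0.5 * float(e @ (iS_diag * e)) + 0.5 * float(group_sizes @ h) \
            - 0.5 * n * LOG2PI
        if p:
            d = mu_free - mu0
            F += -0.5 * float(d @ Pi0 @ d) - 0.5 * logdet_S0 + 0.5 * _logdet(Sq)
        if fixed_h is None:
            # hyperparameter complexity (Laplace approximation over h)
            dh = h - h0
            F += -0.5 * float(dh @ dh) / v_h
        return F

    def evaluate(theta_full: np.ndarray):
        """g, J, h-update, Sq and F at a parameter vector."""
        g = forward(theta_full)
        if g.shape != y.shape or not np.all(np.isfinite(g)):
            raise ConvergenceError("forward model returned invalid prediction")
        J = _finite_difference_jacobian(forward, theta_full, free,
                                        settings.fd_step, n)
        e = residual(g)
        _, Sq = update_h(e, J)
        F = free_energy(e, Sq, theta_full[free])
        return g, J, e, Sq, F

    try:
        g, J, e, Sq, F = evaluate(theta)
    except Exception as exc:  # unstable at start: no fit possible
        raise ConvergenceError(
            f"free energy not computable at the starting point: {exc}") from exc

    trajectory = [F]
    damping = settings.initial_damping
    consecutive_small = 0
    stalled = False
    for _ in range(settings.max_iterations):
        if p == 0:
            break
        iS_diag = np.concatenate([np.full(group_sizes[k], np.exp(h[k]))
                                  for k in range(n_groups)])
        P = J.T @ (J * iS_diag[:, None]) + Pi0
        grad = J.T @ (iS_diag * e) - Pi0 @ (theta[free] - mu0)
        accepted = False
        for _reject in range(settings.max_rejections + 1):
            reg = P + damping * np.diag(np.maximum(np.diag(P), 1e-12))
            try:
                step = np.linalg.solve(reg, grad)
            except np.linalg.LinAlgError:
                damping *= settings.damping_increase
                continue
            theta_new = theta.copy()
            theta_new[free] = theta[free] + step
            h_backup = h.copy()
            try:
                g2, J2, e2, Sq2, F2 = evaluate(theta_new)
            except Exception:
                h = h_backup
                damping *= settings.damping_increase
                continue
            if F2 >= F:
                theta, g, J, e, Sq = theta_new, g2, J2, e2, Sq2
                dF = F2 - F
                F = F2
                trajectory.append(F)
                damping = max(damping * settings.damping_decrease, 1e-8)
                consecutive_small = consecutive_small + 1 \
                    if dF < settings.convergence_tolerance else 0
                accepted = True
                break
            h = h_backup
            damping *= settings.damping_increase
        if not accepted:
            stalled = True  # no ascent direction left: treat as converged
            break
        if consecutive_small >= settings.converged_after:
            break

    # assemble the full posterior: fixed parameters keep the prior exactly
    mean = theta
    cov = np.zeros((len(prior), len(prior)))
    if p:
        cov[np.ix_(free, free)] = 0.5 * (Sq + Sq.T)
    post = GaussianDensity(list(prior.names), mean, cov, free_energy=F)
    post.meta = {
        "trajectory": [float(x) for x in trajectory],
        "noise_log_precision": h.tolist(),
        "stalled": stalled,
        "iterations": len(trajectory) - 1,
    }
    return post
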