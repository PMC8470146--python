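"""Named multivariate Gaussian densities.

Used uniformly for priors, per-subject posteriors and group-level
posteriors.  A density optionally carries the variational free energy of
the fit that produced it (absent for priors).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["GaussianDensity"]


@dataclass
class GaussianDensity:
    """Mean vector and covariance over named parameters.

    Parameters with exactly zero prior variance are treated as fixed
    ("switched off"): any fitting routine must return them unchanged.

    Attributes
    ----------
    names : list of str
        Ordered parameter labels.
    mean : (M,) ndarray
    cov : (M, M) ndarray
        Symmetric positive semi-definite covariance.
    free_energy : float or None
        Variational free energy of the fit; ``None`` for priors.
    """

    names: list[str]
    mean: np.ndarray
    cov: np.ndarray
    free_energy: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = np.asarray(self.cov, dtype=float)
        m = len(self.names)
        if self.mean.shape != (m,):
            raise ValueError(
                f"mean has shape {self.mean.shape}, expected ({m},)")
        if self.cov.shape != (m, m):
            raise ValueError(
                f"covariance has shape {self.cov.shape}, expected ({m},{m})")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")

    # -- convenience -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def variances(self) -> np.ndarray:
        return np.diag(self.cov).copy()

    def marginal(self, names: Sequence[str]) -> "GaussianDensity":
        idx = [self.index(n) for n in names]
        return GaussianDensity(
            [self.names[i] for i in idx],
            self.mean[idx],
            self.cov[np.ix_(idx, idx)],
            free_energy=self.free_energy,
        )

    def credible_interval(self, name: str, level: float = 0.90) -> tuple[float, float]:
        """Central credible interval for one parameter's marginal."""
        from scipy.stats import norm

        i = self.index(name)
        sd = float(np.sqrt(max(self.cov[i, i], 0.0)))
        z = norm.ppf(0.5 + level / 2.0)
        return (float(self.mean[i]) - z * sd, float(self.mean[i]) + z * sd)

    @staticmethod
    def diagonal(names: Sequence[str], mean, variances) -> "GaussianDensity":
        mean = np.asarray(mean, dtype=float)
        variances = np.asarray(variances, dtype=float)
        return GaussianDensity(list(names), mean, np.diag(variances))

    def to_dict(self) -> dict:
        d = {
            "names": list(self.names),
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
        }
        if self.free_energy is not None:
            d["free_energy"] = float(self.free_energy)
        if self.meta:
            d["meta"] = self.meta
        return d

    @staticmethod
    def from_dict(d: dict) -> "GaussianDensity":
        return GaussianDensity(
            d["names"],
            np.asarray(d["mean"], dtype=float),
            np.asarray(d["cov"], dtype=float),
            free_energy=d.get("free_energy"),
            meta=d.get("meta", {}),
        )
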