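"""Virtual species: elliptical fundamental niche and logistic detection.

The virtual species' fundamental niche is modelled as a Gaussian hill in
environment space.  At an environment ``x`` the finite rate of increase is

    lambda_F(x) = lambda_max * exp(-1/2 * (x - mu)^T Sigma^-1 (x - mu))

so iso-fitness contours are ellipses centred on the niche optimum ``mu``,
with size and orientation governed by the covariance-like matrix ``Sigma``.
The probability that a visit to environment ``x`` yields a present-and-
detected occurrence follows a logistic curve in lambda_F,

    P_d = 1 / (1 + exp(-10 * (lambda_F - 0.5)))

which is ~0 where the population cannot persist (lambda_F ~ 0) and
saturates near 1 once lambda_F exceeds replacement (lambda_F >~ 1).

The default parameterisation is a montane species in a two-dimensional
climate space of mean annual temperature (degC) and annual rainfall (mm):
lambda_max = 2.5, mu = (7.5, 1800), Sigma = [[2, -950], [-950, 800000]]
(cooler sites in this species' range tend to be wetter, hence the negative
covariance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import expit

from ._util import check_matrix
from .errors import DomainError, InvalidParameterError

__all__ = [
    "NicheParams",
    "DEFAULT_LAMBDA_MAX",
    "DEFAULT_MU",
    "DEFAULT_SIGMA",
    "niche_growth_rate",
    "detection_probability",
]

DEFAULT_LAMBDA_MAX = 2.5
DEFAULT_MU = (7.5, 1800.0)
DEFAULT_SIGMA = ((2.0, -950.0), (-950.0, 800000.0))


@dataclass(frozen=True)
class NicheParams:
    """Parameters of the elliptical fundamental niche.

    Attributes
    ----------
    lambda_max : float
        Maximum finite rate of increase, attained at the niche optimum.
    mu : (n,) ndarray
        Optimal environmental conditions (the niche centre).
    sigma : (n, n) ndarray
        Symmetric positive-definite matrix setting niche size/orientation.
    """

    lambda_max: float = DEFAULT_LAMBDA_MAX
    mu: np.ndarray = field(default=DEFAULT_MU)
    sigma: np.ndarray = field(default=DEFAULT_SIGMA)

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        if not np.isfinite(self.lambda_max) or self.lambda_max <= 0:
            raise InvalidParameterError("lambda_max must be a positive real")
        if mu.ndim != 1 or sigma.shape != (mu.size, mu.size):
            raise InvalidParameterError(
                f"mu (length {mu.size}) and sigma (shape {sigma.shape}) are inconsistent"
            )
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(sigma))):
            raise InvalidParameterError("mu and sigma must be finite")
        if not np.allclose(sigma, sigma.T, rtol=1e-10, atol=0):
            raise InvalidParameterError("sigma must be symmetric")
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as exc:
            raise InvalidParameterError(
                "sigma must be positive definite (all eigenvalues > 0)"
            ) from exc
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "_chol", chol)

    @property
    def dim(self) -> int:
        """Number of environmental dimensions n."""
        return self.mu.size

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "lambda_max": float(self.lambda_max),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NicheParams":
        return cls(lambda_max=d["lambda_max"], mu=d["mu"], sigma=d["sigma"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "NicheParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _squared_distance(params: NicheParams, X: np.ndarray) -> np.ndarray:
    # (x - mu)^T Sigma^-1 (x - mu) via a triangular solve against the
    # cached Cholesky factor; avoids forming Sigma^-1 explicitly.
    dev = X - params.mu
    z = solve_triangular(params._chol, dev.T, lower=True)
    return np.einsum("ij,ij->j", z, z)


def niche_growth_rate(params: NicheParams, points) -> np.ndarray | float:
    """Finite rate of increase lambda_F at one or more environment points.

    Parameters
    ----------
    params : NicheParams
    points : array-like, shape (m, n) or (n,)

    Returns
    -------
    ndarray of shape (m,), or a scalar for a single 1-D point; values lie
    in (0, lambda_max], with the maximum attained exactly at ``mu``.
    """
    single = np.asarray(points).ndim == 1
    X = check_matrix(points, n=params.dim)
    lam = params.lambda_max * np.exp(-0.5 * _squared_distance(params, X))
    return float(lam[0]) if single else lam


def detection_probability(lambda_f) -> np.ndarray | float:
    """Probability of the species being present and detected, P_d(lambda_F).

    Logistic in the growth rate: ``1 / (1 + exp(-10 (lambda_F - 0.5)))``.
    Strictly increasing; ~0.0067 at lambda_F = 0 and ~0.9933 at lambda_F = 1.
    """
    single = np.asarray(lambda_f).ndim == 0
    lam = np.atleast_1d(np.asarray(lambda_f, dtype=float))
    if np.any(~np.isfinite(lam)) or np.any(lam < 0):
        raise DomainError("lambda_f must be finite and non-negative")
    p = expit(10.0 * (lam - 0.5))
    return float(p[0]) if single else p
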