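"""Mahalanobis-distance niche model: D^2 and chi-squared probabilities.

Given a fitted location/scatter pair, the squared Mahalanobis distance

    D^2(x) = (x - loc)^T scatter^-1 (x - loc)

measures how far an environment point lies from the centre of the fitted
distribution.  Under multivariate normality D^2 follows a chi-squared
distribution with n degrees of freedom, so its CDF converts D^2 into
P(chi2_n <= D^2) — an outlier probability — and the survival function into
P(chi2_n > D^2), the probability of the environment lying inside the
fundamental niche, which is the quantity mapped in niche modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.stats import chi2

from ._util import check_matrix
from .errors import DegenerateModelError, DomainError, ShapeError
from .location_scatter import LocationScatter

__all__ = ["NichePrediction", "mahalanobis_d2", "niche_probability",
           "predict", "predict_grid", "grid_frame"]


@dataclass(frozen=True)
class NichePrediction:
    """D^2 plus its chi-squared probability transforms at a set of points.

    ``p_inside`` is P(chi2_dof <= D^2) (outlier probability) and
    ``p_niche`` its complement P(chi2_dof > D^2) (niche probability);
    they sum to one elementwise.
    """

    d2: np.ndarray
    p_inside: np.ndarray
    p_niche: np.ndarray
    dof: int


def mahalanobis_d2(ls: LocationScatter, points) -> np.ndarray:
    """Squared Mahalanobis distances of points under a fitted estimate."""
    X = check_matrix(points, n=ls.dim)
    try:
        L = np.linalg.cholesky(ls.scatter)
    except np.linalg.LinAlgError as exc:
        raise DegenerateModelError("scatter is not positive definite") from exc
    z = solve_triangular(L, (X - ls.location).T, lower=True)
    return np.einsum("ij,ij->j", z, z)


def niche_probability(d2, dof: int, invert: bool = True) -> np.ndarray:
    """Chi-squared probability transform of squared Mahalanobis distances.

    ``invert=True`` returns P(chi2_dof > D^2), the niche probability used
    for mapping habitat suitability; ``invert=False`` returns the outlier
    probability P(chi2_dof <= D^2).  For dof = 2 these reduce to
    exp(-D^2/2) and 1 - exp(-D^2/2).
    """
    d2 = np.asarray(d2, dtype=float)
    if dof < 1:
        raise DomainError("dof must be >= 1")
    if np.any(~np.isfinite(d2)) or np.any(d2 < 0):
        raise DomainError("d2 must be finite and non-negative")
    return chi2.sf(d2, df=dof) if invert else chi2.cdf(d2, df=dof)


def predict(ls: LocationScatter, points) -> NichePrediction:
    """Full prediction (D^2 and both probabilities) at a set of points."""
    d2 = mahalanobis_d2(ls, points)
    return NichePrediction(
        d2=d2,
        p_inside=niche_probability(d2, ls.dim, invert=False),
        p_niche=niche_probability(d2, ls.dim, invert=True),
        dof=ls.dim,
    )


def _check_axis(axis, name):
    a = np.asarray(axis, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise ShapeError(f"{name} must be a non-empty 1-D vector")
    if np.any(np.diff(a) <= 0):
        raise ShapeError(f"{name} must be strictly increasing")
    return a


def predict_grid(ls: LocationScatter, axis1, axis2) -> np.ndarray:
    """Niche probability P(chi2_2 > D^2) over the Cartesian product of two
    environment axes; row-major array of shape (len(axis1), len(axis2))."""
    a1 = _check_axis(axis1, "axis1")
    a2 = _check_axis(axis2, "axis2")
    g1, g2 = np.meshgrid(a1, a2, indexing="ij")
    pts = np.column_stack([g1.ravel(), g2.ravel()])
    d2 = mahalanobis_d2(ls, pts)
    return niche_probability(d2, ls.dim, invert=True).reshape(a1.size, a2.size)


def grid_frame(ls: LocationScatter, axis1, axis2) -> pd.DataFrame:
    """Long-format grid prediction: columns axis1, axis2, d2, p_niche."""
    a1 = _check_axis(axis1, "axis1")
    a2 = _check_axis(axis2, "axis2")
    g1, g2 = np.meshgrid(a1, a2, indexing="ij")
    pts = np.column_stack([g1.ravel(), g2.ravel()])
    d2 = mahalanobis_d2(ls, pts)
    return pd.DataFrame({
        "axis1": pts[:, 0],
        "axis2": pts[:, 1],
        "d2": d2,
        "p_niche": niche_probability(d2, ls.dim, invert=True),
    })
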