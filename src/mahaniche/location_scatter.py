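"""Multivariate location and scatter: sample, MCD and MVE estimators.

Three ways of summarising an occurrence matrix ``X`` (m points in an
n-dimensional environment space) by a location vector and scatter matrix:

* ``estimate_sample`` — column means and the (m-1)-denominator sample
  variance-covariance matrix; efficient but sensitive to outliers.
* ``estimate_mcd`` — minimum covariance determinant: the h-point subset
  whose covariance matrix has the smallest determinant.  Fast mode uses
  the FAST-MCD scheme (elemental starts refined by concentration steps);
  exhaustive mode enumerates every h-subset and is intended as a
  brute-force oracle for small samples.
* ``estimate_mve`` — minimum volume ellipsoid: the smallest ellipsoid
  (by the resampling algorithm over elemental subsets) covering h points.

The retained fraction k = h/m controls robustness: k near 0.5 gives the
most outlier-resistant estimates, while at k = 1 both robust methods
coincide with the classical sample estimator.  Raw robust scatters are
optionally rescaled for consistency with the multivariate normal model so
that chi-squared probabilities are comparable across methods.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import chi2

from ._util import as_generator, check_matrix
from .errors import (
    DegenerateModelError,
    DegenerateSampleError,
    InfeasibleSubsetError,
    InvalidParameterError,
    SubsetEnumerationError,
)

__all__ = [
    "LocationScatter",
    "EstimatorConfig",
    "subset_size",
    "estimate_sample",
    "estimate_mcd",
    "estimate_mve",
]

_EXHAUSTIVE_CAP = 10**6
_N_KEEP = 10  # candidates carried from the short to the full C-step phase


@dataclass(frozen=True)
class LocationScatter:
    """A fitted multivariate location vector and scatter matrix.

    ``h``, ``retained_indices`` and ``objective`` are populated by the
    robust estimators only: the subset size actually used, the (sorted)
    row indices of the retained subset, and the optimisation objective
    (covariance determinant for MCD; det(C) * inflation^n for MVE),
    always recorded before any consistency rescaling.
    """

    location: np.ndarray
    scatter: np.ndarray
    method: str
    h: int | None = None
    retained_indices: np.ndarray | None = None
    objective: float | None = None

    def __post_init__(self) -> None:
        loc = np.atleast_1d(np.asarray(self.location, dtype=float))
        S = np.atleast_2d(np.asarray(self.scatter, dtype=float))
        if self.method not in ("sample", "mcd", "mve"):
            raise InvalidParameterError(f"unknown method {self.method!r}")
        if S.shape != (loc.size, loc.size):
            raise InvalidParameterError("location/scatter dimensions inconsistent")
        try:
            np.linalg.cholesky(S)
        except np.linalg.LinAlgError as exc:
            raise DegenerateModelError("scatter must be positive definite") from exc
        idx = self.retained_indices
        if idx is not None:
            idx = np.asarray(idx, dtype=int)
            if np.unique(idx).size != idx.size:
                raise InvalidParameterError("retained_indices must be distinct")
        object.__setattr__(self, "location", loc)
        object.__setattr__(self, "scatter", S)
        object.__setattr__(self, "retained_indices", idx)

    @property
    def dim(self) -> int:
        return self.location.size

    def to_dict(self) -> dict:
        return {
            "location": self.location.tolist(),
            "scatter": self.scatter.tolist(),
            "method": self.method,
            "h": None if self.h is None else int(self.h),
            "objective": None if self.objective is None else float(self.objective),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LocationScatter":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["location"], d["scatter"], d["method"], h=d.get("h"),
                   objective=d.get("objective"))


@dataclass(frozen=True)
class EstimatorConfig:
    """Tuning knobs for the robust estimators.

    k : retained proportion, h = floor(k*m); None selects the maximally
        robust default h = floor((m+n+1)/2).
    n_trials : number of elemental-subset starts (fast mode).  When the
        number of distinct elemental subsets does not exceed n_trials they
        are all enumerated deterministically instead of sampled.
    max_csteps : cap on concentration steps per start (convergence is
        normally reached in well under ten).
    exhaustive : enumerate every h-subset (MCD) / elemental subset (MVE);
        brute-force oracle mode, permitted only for small subset spaces.
    reweight : apply a one-step reweighting after the subset search (the
        convention of classical robust-covariance software): the final
        location/scatter are the plain mean/covariance of every point
        whose D^2 under the inflated best-subset estimate falls below an
        adaptive 97.5% chi-squared cut.  This recovers near-classical
        efficiency on clean data while still excluding gross outliers.
        Skipped at h = m, where the robust estimators reduce to the
        classical one.  With ``reweight=False`` the raw subset estimate
        is returned instead.
    rescale : chi-squared consistency factor applied to the *raw* robust
        scatter (so D^2 quantiles match the normal model) when
        ``reweight=False``; ignored otherwise.
    """

    k: float | None = None
    n_trials: int = 500
    max_csteps: int = 100
    exhaustive: bool = False
    reweight: bool = True
    rescale: bool = True
    seed: int | np.random.Generator | None = 0

    def __post_init__(self) -> None:
        if self.k is not None and not (0.5 < self.k <= 1.0):
            raise InvalidParameterError("k must lie in (0.5, 1]")
        if self.n_trials < 1 or self.max_csteps < 1:
            raise InvalidParameterError("n_trials and max_csteps must be >= 1")


def subset_size(m: int, n: int, k: float | None = None) -> int:
    """Subset size h used by the robust estimators.

    ``h = floor(k*m)`` when a retained proportion k is given, otherwise the
    maximally robust default ``h = floor((m+n+1)/2)``; the result is clamped
    to the feasible range [n+1, m].  A tiny additive tolerance guards the
    floor against binary float representation (0.95*20 is 18.999...96).
    """
    if m < n + 1:
        raise InfeasibleSubsetError(f"no feasible subset: m={m} < n+1={n + 1}")
    if k is not None:
        if not (0.5 < k <= 1.0):
            raise InvalidParameterError("k must lie in (0.5, 1]")
        h = math.floor(k * m + 1e-9)
    else:
        h = (m + n + 1) // 2
    return min(max(h, n + 1), m)


# ----------------------------------------------------------------------
# internals

def _mean_cov(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and (len-1)-denominator covariance of the rows of X."""
    loc = X.mean(axis=0)
    dev = X - loc
    return loc, dev.T @ dev / (len(X) - 1)


def _pd_inv_det(S: np.ndarray):
    """(S^-1, det S) via Cholesky, or (None, None) if S is not PD."""
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        return None, None
    d = np.diagonal(L)
    if np.any(d <= 0) or not np.all(np.isfinite(L)):
        return None, None
    try:
        inv = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        # Cholesky can succeed on matrices the LU factorisation flags as
        # exactly singular (e.g. duplicated points); treat as degenerate.
        return None, None
    return inv, float(np.prod(d) ** 2)


def _d2_all(X: np.ndarray, loc: np.ndarray, inv: np.ndarray) -> np.ndarray:
    dev = X - loc
    return np.einsum("ij,jk,ik->i", dev, inv, dev)


def _smallest_h(d2: np.ndarray, h: int) -> np.ndarray:
    # ties broken by lowest row index (stable sort)
    return np.argsort(d2, kind="stable")[:h]


def _concentrate(X, h, loc, S, max_csteps, det_trace=None):
    """Iterate C-steps from (loc, S) until the determinant stops decreasing.

    Returns (idx, loc, S, det) of the final h-subset, or None if a
    degenerate subset is encountered.  Each step retains the h points of
    smallest D^2 under the current estimate and re-estimates; the
    covariance determinant is non-increasing along the iteration (the
    per-step determinants are appended to ``det_trace`` when given).
    """
    prev_det = np.inf
    out = None
    for _ in range(max_csteps):
        inv, _ = _pd_inv_det(S)
        if inv is None:
            return out
        d2 = _d2_all(X, loc, inv)
        idx = _smallest_h(d2, h)
        loc, S = _mean_cov(X[idx])
        _, det = _pd_inv_det(S)
        if det is None:
            return out
        if det_trace is not None:
            det_trace.append(det)
        out = (idx, loc, S, det)
        if det >= prev_det * (1.0 - 1e-12):
            break
        prev_det = det
    return out


def _elemental_starts(m, n, n_trials, rng):
    """Yield elemental (n+1)-point index subsets: all of them when few,
    otherwise n_trials random draws."""
    if math.comb(m, n + 1) <= n_trials:
        yield from (np.asarray(c) for c in itertools.combinations(range(m), n + 1))
    else:
        for _ in range(n_trials):
            yield rng.choice(m, size=n + 1, replace=False)


def _initial_estimate(X, subset, rng):
    """Mean/cov of an elemental subset, extended by random extra points
    while singular (FAST-MCD convention); None if still singular at m."""
    m = len(X)
    idx = list(subset)
    while True:
        loc, S = _mean_cov(X[idx])
        if _pd_inv_det(S)[0] is not None:
            return loc, S
        if len(idx) == m:
            return None
        remaining = np.setdiff1d(np.arange(m), idx)
        idx.append(int(rng.choice(remaining)))


def _mcd_consistency(X, idx, loc, S, n):
    """Median-D^2 chi-squared consistency factor for the raw MCD scatter."""
    inv, _ = _pd_inv_det(S)
    d2 = _d2_all(X[idx], loc, inv)
    return float(np.median(d2)) / chi2.ppf(0.5, df=n)


def _reweight(X, idx, h):
    """One-step reweighting from the best h-subset.

    The subset covariance is inflated by the finite-sample factor
    (1 + 15/(m-n))^2; every point whose D^2 under that estimate lies
    below cut = chi2(0.975; n) * quantile(D^2, h/m) / chi2(h/m; n) is
    retained, and the final estimate is the plain mean/covariance of the
    retained points.  Returns (location, scatter, retained_indices).
    """
    m, n = X.shape
    loc_b, S_b = _mean_cov(X[idx])
    rcov = S_b * (1.0 + 15.0 / (m - n)) ** 2
    inv, _ = _pd_inv_det(rcov)
    if inv is None:
        raise DegenerateSampleError("best-subset covariance is singular")
    dist = _d2_all(X, loc_b, inv)
    q = h / m
    cut = chi2.ppf(0.975, df=n) * float(np.quantile(dist, q)) / chi2.ppf(q, df=n)
    sel = np.flatnonzero(dist < cut)
    if len(sel) < n + 1:
        raise DegenerateSampleError("reweighting retained fewer than n+1 points")
    loc, S = _mean_cov(X[sel])
    if _pd_inv_det(S)[0] is None:
        raise DegenerateSampleError("reweighted covariance is singular")
    return loc, S, sel


# ----------------------------------------------------------------------
# estimators

def estimate_sample(X) -> LocationScatter:
    """Classical estimator: column means + sample variance-covariance."""
    X = check_matrix(X)
    m, n = X.shape
    if m < n + 1:
        raise DegenerateSampleError(f"need at least n+1={n + 1} points, got {m}")
    loc, S = _mean_cov(X)
    if _pd_inv_det(S)[0] is None:
        raise DegenerateSampleError("sample covariance is singular")
    return LocationScatter(loc, S, "sample")


def estimate_mcd(X, config: EstimatorConfig | None = None) -> LocationScatter:
    """Minimum covariance determinant estimator.

    Fast mode follows FAST-MCD: elemental (n+1)-point starts, two
    concentration steps each, then full concentration of the best few
    candidates; the winner is the h-subset with the smallest covariance
    determinant.  Exhaustive mode enumerates every h-subset (oracle for
    small m).  Requires m >= 5n for a usable breakdown/accuracy trade-off.
    """
    config = config or EstimatorConfig()
    X = check_matrix(X)
    m, n = X.shape
    if m < 5 * n:
        raise InfeasibleSubsetError(f"MCD requires m >= 5n = {5 * n}, got m={m}")
    h = subset_size(m, n, config.k)

    if config.exhaustive:
        best = None
        if math.comb(m, h) > _EXHAUSTIVE_CAP:
            raise SubsetEnumerationError(
                f"C({m},{h}) exceeds the exhaustive-mode cap of {_EXHAUSTIVE_CAP}"
            )
        for comb in itertools.combinations(range(m), h):
            idx = np.asarray(comb)
            loc, S = _mean_cov(X[idx])
            _, det = _pd_inv_det(S)
            if det is None:
                continue
            if best is None or det < best[3]:
                best = (idx, loc, S, det)
    elif h == m:
        loc, S = _mean_cov(X)
        _, det = _pd_inv_det(S)
        best = None if det is None else (np.arange(m), loc, S, det)
    else:
        rng = as_generator(config.seed)
        shortlist = []
        for subset in _elemental_starts(m, n, config.n_trials, rng):
            init = _initial_estimate(X, subset, rng)
            if init is None:
                continue
            cand = _concentrate(X, h, *init, max_csteps=2)
            if cand is not None:
                shortlist.append(cand)
        shortlist.sort(key=lambda c: c[3])
        best = None
        for cand in shortlist[:_N_KEEP]:
            refined = _concentrate(X, h, cand[1], cand[2], config.max_csteps)
            if refined is None:
                continue
            if best is None or refined[3] < best[3]:
                best = refined

    if best is None:
        raise DegenerateSampleError("every candidate h-subset was singular")
    idx, loc, S, det = best
    if config.reweight and h < m:
        loc, S, idx = _reweight(X, idx, h)
    elif not config.reweight and config.rescale:
        S = S * _mcd_consistency(X, idx, loc, S, n)
    return LocationScatter(loc, S, "mcd", h=h,
                           retained_indices=np.sort(idx), objective=det)


def estimate_mve(X, config: EstimatorConfig | None = None) -> LocationScatter:
    """Minimum volume ellipsoid estimator (resampling algorithm).

    Each elemental (n+1)-point subset proposes an ellipsoid shape: subset
    mean c and covariance C, inflated by lambda = h-th smallest Mahalanobis
    D^2 of the full sample under (c, C) so that it covers h points.  The
    candidate minimising the volume objective det(C) * lambda^n wins;
    scatter = lambda * C, optionally divided by the chi-squared h/m
    quantile for consistency with the normal model.
    """
    config = config or EstimatorConfig()
    X = check_matrix(X)
    m, n = X.shape
    h = subset_size(m, n, config.k)

    if config.exhaustive:
        if math.comb(m, n + 1) > _EXHAUSTIVE_CAP:
            raise SubsetEnumerationError(
                f"C({m},{n + 1}) exceeds the exhaustive-mode cap of {_EXHAUSTIVE_CAP}"
            )
        subsets = (np.asarray(c) for c in itertools.combinations(range(m), n + 1))
    else:
        rng = as_generator(config.seed)
        subsets = _elemental_starts(m, n, config.n_trials, rng)

    best = None
    for subset in subsets:
        loc, C = _mean_cov(X[subset])
        inv, detC = _pd_inv_det(C)
        if inv is None:
            continue
        d2 = _d2_all(X, loc, inv)
        lam = float(np.sort(d2, kind="stable")[h - 1])
        obj = detC * lam**n
        if lam <= 0 or not np.isfinite(obj):
            continue
        if best is None or obj < best[4]:
            best = (loc, C, lam, d2, obj)
    if best is None:
        raise DegenerateSampleError("every elemental subset was singular")

    loc, C, lam, d2, obj = best
    idx = np.sort(_smallest_h(d2, h))
    if config.reweight and h < m:
        loc, S, idx = _reweight(X, idx, h)
    else:
        S = lam * C
        if not config.reweight and config.rescale:
            # q = h/m quantile; continuity-corrected at h = m where the
            # raw quantile would be 1 and the factor unbounded
            q = h / m if h < m else (m - 0.5) / m
            S = S / chi2.ppf(q, df=n)
    return LocationScatter(loc, S, "mve", h=h, retained_indices=idx, objective=obj)


def read_occurrence_csv(path, columns: list[str] | None = None) -> np.ndarray:
    """Load an m x n occurrence matrix from a headered numeric CSV.

    Non-numeric columns (e.g. a provenance label column) are dropped unless
    ``columns`` explicitly names the environment columns to keep.
    """
    import pandas as pd

    df = pd.read_csv(path)
    if columns is not None:
        df = df[columns]
    else:
        df = df.select_dtypes(include=[np.number])
    return check_matrix(df.to_numpy(dtype=float), name=str(path))
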