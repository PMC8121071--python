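"""Synthetic regional climate space for the error and bias experiments.

The contamination experiments need a finite "sampling space": the set of
climates actually available in the virtual species' region, standing in
for the cells of a gridded temperature/rainfall climatology.  It is
generated as a bounded mixture of bivariate normal components, built so
that (like a real region's climate space relative to a species' niche)

* the space only partially overlaps the fundamental niche — a uniformly
  drawn point is usually a low-detection environment, so uniform draws
  act as errors that represent the region rather than the niche; and
* the bulk of the space's density sits off-centre from the niche optimum,
  so detection-weighted draws concentrate on the common climates that
  overlap one flank of the niche — the signature of sampling bias.

``draw_uniform`` emulates errors (random locations in the region) and
``draw_biased`` emulates bias (random locations filtered by detection
probability, via rejection sampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import as_generator, check_matrix
from .errors import BiasInfeasibleError, EmptySpaceError, InvalidParameterError
from .virtual_niche import NicheParams, detection_probability, niche_growth_rate

__all__ = ["SamplingSpace", "SpaceConfig", "generate_space",
           "draw_uniform", "draw_biased"]

_REJECTION_CAP = 10**6


@dataclass(frozen=True)
class SamplingSpace:
    """A finite weighted set of environment points (emulated grid cells)."""

    points: np.ndarray
    weights: np.ndarray = None

    def __post_init__(self) -> None:
        pts = check_matrix(self.points, name="points")
        if len(pts) < 100:
            raise InvalidParameterError("a sampling space needs >= 100 points")
        if self.weights is None:
            w = np.full(len(pts), 1.0 / len(pts))
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(pts),) or np.any(w < 0):
                raise InvalidParameterError("weights must be non-negative, one per point")
            total = w.sum()
            if not np.isclose(total, 1.0, atol=1e-9):
                if total <= 0:
                    raise InvalidParameterError("weights must have positive mass")
                w = w / total
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.points)

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "temperature": self.points[:, 0],
            "rainfall": self.points[:, 1],
            "weight": self.weights,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SamplingSpace":
        """Load a space from CSV: temperature, rainfall[, weight] columns."""
        df = pd.read_csv(path)
        pts = df[["temperature", "rainfall"]].to_numpy(dtype=float)
        w = df["weight"].to_numpy(dtype=float) if "weight" in df else None
        return cls(pts, w)


@dataclass(frozen=True)
class SpaceConfig:
    """Truncated bivariate-normal mixture defining the synthetic region.

    Defaults emulate a temperate, topographically varied region whose
    common climates are cooler and drier than the default niche optimum
    (7.5 degC, 1800 mm): the dominant component sits far from the optimum
    in the low-temperature/low-rainfall direction, the minor component
    overlaps the niche, and hard bounds truncate physically implausible
    values.
    """

    n_points: int = 4000
    means: tuple = ((4.5, 700.0), (8.3, 1250.0))
    covs: tuple = (
        ((5.0, 800.0), (800.0, 360000.0)),
        ((1.8, 300.0), (300.0, 250000.0)),
    )
    mix: tuple = (0.8, 0.2)
    temp_bounds: tuple = (-2.0, 16.0)
    rain_bounds: tuple = (50.0, 6000.0)

    def __post_init__(self) -> None:
        if self.n_points < 100:
            raise InvalidParameterError("n_points must be >= 100")
        if len(self.means) != len(self.covs) or len(self.means) != len(self.mix):
            raise InvalidParameterError("means, covs and mix must align")
        if not np.isclose(sum(self.mix), 1.0) or any(p <= 0 for p in self.mix):
            raise InvalidParameterError("mixing proportions must be positive and sum to 1")


def generate_space(config: SpaceConfig | None = None, seed=0) -> SamplingSpace:
    """Draw a finite sampling space from the truncated mixture.

    Deterministic given the seed; points outside the hard bounds are
    rejected and redrawn.  Raises EmptySpaceError if the bounds exclude
    essentially all mixture mass.
    """
    config = config or SpaceConfig()
    rng = as_generator(seed)
    (t_lo, t_hi), (r_lo, r_hi) = config.temp_bounds, config.rain_bounds
    collected = []
    n_have = 0
    attempts = 0
    while n_have < config.n_points:
        batch = max(2 * (config.n_points - n_have), 256)
        attempts += batch
        if attempts > max(100 * config.n_points, _REJECTION_CAP):
            raise EmptySpaceError("bounds reject essentially all mixture mass")
        comp = rng.choice(len(config.mix), size=batch, p=np.asarray(config.mix))
        pts = np.empty((batch, 2))
        for c in range(len(config.mix)):
            sel = comp == c
            if sel.any():
                pts[sel] = rng.multivariate_normal(
                    np.asarray(config.means[c]), np.asarray(config.covs[c]),
                    size=int(sel.sum()), method="cholesky")
        ok = ((pts[:, 0] >= t_lo) & (pts[:, 0] <= t_hi)
              & (pts[:, 1] >= r_lo) & (pts[:, 1] <= r_hi))
        collected.append(pts[ok])
        n_have += int(ok.sum())
    pts = np.concatenate(collected)[: config.n_points]
    return SamplingSpace(pts)


def draw_uniform(space: SamplingSpace, count: int, seed=0) -> np.ndarray:
    """Sample ``count`` environment points from the space (weighted, with
    replacement) — the error model: random locations within the region."""
    if count < 0:
        raise InvalidParameterError("count must be >= 0")
    rng = as_generator(seed)
    if count == 0:
        return np.empty((0, space.points.shape[1]))
    idx = rng.choice(len(space), size=count, replace=True, p=space.weights)
    return space.points[idx]


def draw_biased(space: SamplingSpace, params: NicheParams, count: int,
                seed=0, max_attempts: int = _REJECTION_CAP) -> np.ndarray:
    """Detection-weighted draws from the space — the bias model.

    Rejection sampling: draw a random location in the region, accept it
    with probability P_d(lambda_F) (the chance the species is present and
    detected there), repeat until ``count`` accepted.  Raises
    BiasInfeasibleError when acceptance is essentially impossible.
    """
    if count < 0:
        raise InvalidParameterError("count must be >= 0")
    rng = as_generator(seed)
    n_dim = space.points.shape[1]
    if count == 0:
        return np.empty((0, n_dim))
    accepted = []
    n_have = 0
    attempts = 0
    while n_have < count:
        batch = min(max(4 * (count - n_have), 256), max_attempts)
        if attempts + batch > max_attempts:
            raise BiasInfeasibleError(
                f"rejection sampling exceeded {max_attempts} attempts "
                f"({n_have}/{count} accepted)")
        attempts += batch
        cand = draw_uniform(space, batch, rng)
        p = detection_probability(niche_growth_rate(params, cand))
        keep = rng.random(batch) < p
        accepted.append(cand[keep])
        n_have += int(keep.sum())
    return np.concatenate(accepted)[:count]
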