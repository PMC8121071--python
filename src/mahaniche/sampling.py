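"""Occurrence-sample generation: idealised sampling and contamination.

Idealised sampling draws candidate locations from the niche's own
bivariate normal distribution N(mu, Sigma) and keeps each with
probability P_d(lambda_F) — the species must be present and detected —
so accepted occurrences concentrate towards the niche centre.

Contamination then replaces a fraction of an idealised sample with
draws from a regional sampling space: uniform draws model *errors*
(records that are random locations in the region, unrelated to the
niche) and detection-weighted draws model *bias* (records concentrated
in commonly sampled climates that overlap the niche).  Replacement keeps
the sample size m fixed so contamination level is the only thing varied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import as_generator, check_matrix
from .errors import DomainError, InvalidParameterError, SamplingInfeasibleError
from .synthetic_space import SamplingSpace, draw_biased, draw_uniform
from .virtual_niche import NicheParams, detection_probability, niche_growth_rate

__all__ = ["OccurrenceSample", "sample_idealised", "contaminate"]

_REJECTION_CAP = 10**6
PROVENANCE_LABELS = ("idealised", "error", "bias")


@dataclass(frozen=True)
class OccurrenceSample:
    """An m x n matrix of environment coordinates with per-row provenance."""

    X: np.ndarray
    provenance: np.ndarray

    def __post_init__(self) -> None:
        X = check_matrix(self.X, name="X")
        prov = np.asarray(self.provenance, dtype=object)
        if prov.shape != (len(X),):
            raise InvalidParameterError("one provenance label per row required")
        bad = set(prov) - set(PROVENANCE_LABELS)
        if bad:
            raise InvalidParameterError(f"unknown provenance labels: {bad}")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "provenance", prov)

    @property
    def m(self) -> int:
        return len(self.X)

    @property
    def n(self) -> int:
        return self.X.shape[1]

    def label_counts(self) -> dict:
        labels, counts = np.unique(self.provenance.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def to_csv(self, path) -> None:
        cols = (["temperature", "rainfall"] if self.n == 2
                else [f"var{j + 1}" for j in range(self.n)])
        df = pd.DataFrame(self.X, columns=cols)
        df["provenance"] = self.provenance.astype(str)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OccurrenceSample":
        df = pd.read_csv(path)
        prov = df.pop("provenance").to_numpy()
        return cls(df.to_numpy(dtype=float), prov)


def sample_idealised(params: NicheParams, m: int, seed=0,
                     max_attempts: int = _REJECTION_CAP) -> OccurrenceSample:
    """Idealised detection-filtered sample of m occurrences.

    Candidates x ~ N(mu, Sigma) are accepted with probability
    P_d(lambda_F(x)); with the default niche roughly three quarters of
    candidates are accepted, so the iteration cap is never approached.
    """
    if m < 1:
        raise InvalidParameterError("m must be >= 1")
    rng = as_generator(seed)
    accepted = []
    n_have = 0
    attempts = 0
    while n_have < m:
        batch = min(max(2 * (m - n_have), 128), max_attempts)
        if attempts + batch > max_attempts:
            raise SamplingInfeasibleError(
                f"idealised sampling exceeded {max_attempts} attempts")
        attempts += batch
        cand = rng.multivariate_normal(params.mu, params.sigma, size=batch,
                                       method="cholesky")
        p = detection_probability(niche_growth_rate(params, cand))
        keep = rng.random(batch) < p
        accepted.append(cand[keep])
        n_have += int(keep.sum())
    X = np.concatenate(accepted)[:m]
    return OccurrenceSample(X, np.full(m, "idealised", dtype=object))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def contaminate(sample: OccurrenceSample, space: SamplingSpace,
                params: NicheParams, error_frac: float = 0.0,
                bias_frac: float = 0.0, seed=0) -> OccurrenceSample:
    """Replace fractions of a sample with error and/or bias draws.

    ``round(error_frac * m)`` rows are replaced by uniform draws from the
    space (label "error") and ``round(bias_frac * m)`` further rows by
    detection-weighted draws (label "bias"); replaced positions are chosen
    uniformly without replacement and the sample size is conserved.
    Fractions round half-up, which is exact on the experimental grids
    (multiples of 0.05 at m = 100).
    """
    if not (0.0 <= error_frac <= 1.0 and 0.0 <= bias_frac <= 1.0):
        raise DomainError("error_frac and bias_frac must lie in [0, 1]")
    if error_frac + bias_frac > 1.0 + 1e-12:
        raise DomainError("error_frac + bias_frac must not exceed 1")
    m = sample.m
    n_err = _round_half_up(error_frac * m)
    n_bias = min(_round_half_up(bias_frac * m), m - n_err)
    if n_err + n_bias == 0:
        return OccurrenceSample(sample.X.copy(), sample.provenance.copy())

    rng = as_generator(seed)
    positions = rng.choice(m, size=n_err + n_bias, replace=False)
    X = sample.X.copy()
    prov = sample.provenance.copy()
    if n_err:
        X[positions[:n_err]] = draw_uniform(space, n_err, rng)
        prov[positions[:n_err]] = "error"
    if n_bias:
        X[positions[n_err:]] = draw_biased(space, params, n_bias, rng)
        prov[positions[n_err:]] = "bias"
    return OccurrenceSample(X, prov)
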