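"""Small shared helpers (RNG coercion, matrix validation)."""

from __future__ import annotations

import numpy as np

from .errors import ShapeError

SeedLike = "int | np.random.SeedSequence | np.random.Generator | None"


def as_generator(seed) -> np.random.Generator:
    """Coerce an int, SeedSequence, Generator or None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def check_matrix(points, n: int | None = None, name: str = "points") -> np.ndarray:
    """Validate a 2-D float matrix with finite entries and (optionally) n columns.

    A single 1-D point is promoted to a 1-row matrix.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[np.newaxis, :]
    if X.ndim != 2:
        raise ShapeError(f"{name} must be a 2-D matrix, got ndim={X.ndim}")
    if n is not None and X.shape[1] != n:
        raise ShapeError(f"{name} has {X.shape[1]} columns, expected {n}")
    if not np.all(np.isfinite(X)):
        raise ShapeError(f"{name} contains non-finite values")
    return X
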