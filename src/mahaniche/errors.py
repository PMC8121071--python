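"""Exception hierarchy for niche-model fitting and simulation."""


class NicheModelError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(NicheModelError, ValueError):
    """A model or estimator parameter violates its constraints."""


class ShapeError(NicheModelError, ValueError):
    """Array dimensions are inconsistent with the model."""


class DomainError(NicheModelError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class DegenerateSampleError(NicheModelError, ValueError):
    """A sample (or every candidate subset) has a singular covariance."""


class DegenerateModelError(NicheModelError, ValueError):
    """A fitted scatter matrix is not positive definite."""


class InfeasibleSubsetError(NicheModelError, ValueError):
    """The requested subset size h cannot be realised for this sample."""


class SubsetEnumerationError(NicheModelError, ValueError):
    """Exhaustive enumeration was requested on too large a subset space."""


class EmptySpaceError(NicheModelError, RuntimeError):
    """Sampling-space bounds exclude essentially all mixture mass."""


class BiasInfeasibleError(NicheModelError, RuntimeError):
    """Detection-weighted rejection sampling cannot accept any point."""


class SamplingInfeasibleError(NicheModelError, RuntimeError):
    """Idealised rejection sampling exceeded its iteration cap."""


class UndefinedCorrelationError(NicheModelError, ValueError):
    """Pearson/Spearman correlation is undefined (a constant vector)."""
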