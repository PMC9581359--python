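"""Exception hierarchy shared across the package."""


class StochidError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(StochidError):
    """A required column or field could not be resolved in the input."""


class ValidationError(StochidError):
    """Input data violates a structural invariant (e.g. non-monotone time)."""


class EnsembleError(StochidError):
    """A trial ensemble is too small or inconsistent to analyse."""


class CrossingError(StochidError):
    """No trial intersects the orthogonal plane at a given arc length."""


class InsufficientSamplesError(StochidError):
    """Too few crossing points for a PCA / confidence-ellipse estimate."""


class ProfileError(StochidError):
    """A width or difficulty profile is degenerate (too many invalid planes,
    or a width small enough for the difficulty integral to diverge)."""
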