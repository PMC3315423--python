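"""Exception hierarchy for morphrel.

All errors raised by the package derive from :class:`MorphrelError` so
callers can catch package failures with a single ``except`` clause.
"""


class MorphrelError(Exception):
    """Base class for all morphrel errors."""


class SchemaError(MorphrelError):
    """A required column is missing or the schema mapping is invalid."""


class ParseError(MorphrelError):
    """A value could not be parsed as a finite number."""


class ValidationError(MorphrelError):
    """A record or table violates a data-model invariant."""


class EmptyDesignError(MorphrelError):
    """No subject has a complete set of centre x visit x hemisphere cells."""


class IncompleteTripletError(MorphrelError):
    """A GM/WM/CSF volume triplet is incomplete for some design cell."""


class AliasingError(MorphrelError):
    """The design matrix is rank deficient (collinear terms)."""


class InsufficientDataError(MorphrelError):
    """Fewer observations than model parameters."""


class SaturatedModelError(MorphrelError):
    """The model leaves no residual degrees of freedom (or zero residual
    variance), so F statistics are undefined."""


class UnbalancedDesignError(MorphrelError):
    """The crossed design is not balanced; the moment estimator does not
    apply.  Use ``method='reml'`` instead."""


class DegenerateDesignError(MorphrelError):
    """A factor has a single level, so its variance is not estimable."""


class UndefinedReliabilityError(MorphrelError):
    """Total variance is zero; the reliability ratio is undefined."""


class InsufficientMaskError(MorphrelError):
    """A tissue mask is empty or below the minimum voxel count."""


class GeometryError(MorphrelError):
    """Phantom geometry parameters produce an empty tissue region."""


class ConfigError(MorphrelError):
    """A pipeline configuration is inconsistent with its inputs."""
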