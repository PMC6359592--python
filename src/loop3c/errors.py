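"""Exception hierarchy.

Every error raised by loop3c derives from :class:`Loop3cError`, so callers
can catch the package's failures in one clause.  Most errors are also
``ValueError`` subclasses because they signal invalid inputs.
"""


class Loop3cError(Exception):
    """Base class for all loop3c errors."""


class InvalidInputError(Loop3cError, ValueError):
    """An argument violates a documented precondition."""


class OutOfRangeError(Loop3cError, ValueError):
    """A coordinate falls outside the locus span."""


class InsufficientReplicatesError(InvalidInputError):
    """Fewer replicates than the statistic requires (minimum 2)."""


class MissingNormalizerError(InvalidInputError):
    """No control-locus (normalizer) wells were provided."""


class UnmappedAssayError(InvalidInputError):
    """A junction assay has no entry in the anchor map."""


class InsufficientDataError(InvalidInputError):
    """Too few usable points to fit the background model."""


class DegenerateProximalError(InvalidInputError):
    """The promoter-proximal reference fragment has zero signal."""


class DegenerateControlError(InvalidInputError):
    """An IgG / reference control has zero or negative signal."""


class DegenerateReferenceError(InvalidInputError):
    """A ddPCR reference assay has zero concentration."""


class SaturationError(InvalidInputError):
    """All droplets positive: the Poisson estimate is unbounded."""


class InvalidStandardsError(InvalidInputError):
    """Standard-curve points are degenerate (e.g. equal concentrations)."""


class InvalidScenarioError(InvalidInputError):
    """A synthetic-data scenario is internally inconsistent."""


class FormatError(Loop3cError, ValueError):
    """A file does not conform to the expected plain-text format."""


class ConfigError(Loop3cError, ValueError):
    """A run configuration contains unknown or invalid keys."""
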