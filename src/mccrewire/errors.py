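"""Exception hierarchy shared across the pipeline stages."""


class MccRewireError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(MccRewireError, ValueError):
    """A generator or pipeline configuration value is outside its domain."""


class UnknownKeyError(InvalidConfigError):
    """A configuration document contains a key the schema does not define."""


class OutOfDomainError(InvalidConfigError):
    """A known configuration key carries a value outside its domain."""


class MalformedConfigError(InvalidConfigError):
    """The configuration document could not be parsed at all."""


class InconsistentFixtureError(MccRewireError, ValueError):
    """A synthetic fixture references identifiers absent from its pair."""


class MissingMarkerError(MccRewireError, KeyError):
    """A marker-panel gene is absent from the expression matrix."""


class InsufficientSamplesError(MccRewireError, ValueError):
    """Too few samples for the requested statistic."""


class InsufficientReplicatesError(InsufficientSamplesError):
    """A differential-expression group has fewer than two replicates."""


class InsufficientGenesError(MccRewireError, ValueError):
    """Too few scored genes to build both signature tails."""


class DegenerateProfileError(MccRewireError, ValueError):
    """A perturbation profile has zero variance and cannot be z-scored."""


class DegenerateInputError(MccRewireError, ValueError):
    """All genes are constant; correlations are undefined."""


class InconsistentUniverseError(MccRewireError, ValueError):
    """The stated gene universe does not contain the sets drawn from it."""


class AlignmentError(MccRewireError, ValueError):
    """Time points or identifiers cannot be aligned between inputs."""


class UndefinedCorrelationError(MccRewireError, ValueError):
    """A correlation is requested against a constant vector."""
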