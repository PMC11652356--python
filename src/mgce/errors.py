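"""Exception hierarchy for the MG-CE metric suite."""


class MgceError(Exception):
    """Base class for all package errors."""


class DataValidationError(MgceError):
    """Input violates a structural invariant (bad confidence, non-monotone time, ...)."""


class ParseError(MgceError):
    """A file could not be parsed in the declared dialect."""


class InsufficientDataError(MgceError):
    """Too few samples / too short a window for the requested operation."""


class DegenerateInputError(MgceError):
    """Input is structurally valid but degenerate (all times equal, zero maximum, ...)."""


class DegenerateGeometryError(DegenerateInputError):
    """Zero-length vectors or coincident landmarks where geometry is required."""


class LowResolutionError(MgceError):
    """Pixel extent too small to resolve the requested quantity."""


class SegmentNotFoundError(MgceError):
    """No counting segment satisfying the search constraints exists."""


class NotStartedError(MgceError):
    """The exercise start condition was never met in the recording."""


class NonUniformSamplingError(MgceError):
    """Sampling gaps too large for finite-difference operators; resample first."""


class ConfigError(MgceError):
    """Unknown or ill-typed configuration key."""
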