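"""Exception taxonomy shared across the pipeline."""


class EnmriskError(Exception):
    """Base class for all package-specific errors."""


class RasterFormatError(EnmriskError, ValueError):
    """A raster file is malformed; the message names the offending field."""


class DomainError(EnmriskError, ValueError):
    """Input violates a scientific precondition (out of extent, one class, ...)."""


class DegenerateInputError(EnmriskError, ValueError):
    """Input is technically valid but makes the requested quantity undefined."""


class SchemaError(EnmriskError, KeyError):
    """Columns/layers do not match what a fitted object or stage expects."""


class InfeasibleGeometryError(EnmriskError, RuntimeError):
    """Rejection sampling could not satisfy the spatial constraint."""


class DependencyError(EnmriskError, RuntimeError):
    """A pipeline stage is missing an upstream artifact."""


class ConfigError(EnmriskError, ValueError):
    """A run configuration is invalid (unknown key, bad value, empty member set)."""
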