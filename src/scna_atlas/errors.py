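"""Exception types shared across the package."""


class ScnaAtlasError(Exception):
    """Base class for all package errors."""


class DataError(ScnaAtlasError, ValueError):
    """Malformed, inconsistent or out-of-contract input data."""


class ConfigError(ScnaAtlasError, ValueError):
    """Invalid run configuration or parameters."""


class SimulationError(ScnaAtlasError, RuntimeError):
    """The synthetic-cohort generator could not satisfy its specification."""
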