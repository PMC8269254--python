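"""Exception types shared across the package."""


class MetsynthError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(MetsynthError, ValueError):
    """A generator or pipeline configuration violates its invariants."""


class SchemaError(MetsynthError, ValueError):
    """An input table is missing required columns/ids or has mismatched shape."""


class DegenerateDataError(MetsynthError, ValueError):
    """Data are degenerate for the requested operation (constant column,
    all-zero sample, insufficient replication, rank-deficient design...)."""


class EnumerationLimitError(MetsynthError, RuntimeError):
    """An exact enumeration would exceed the configured size cap."""
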