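"""Exception hierarchy shared across the pipeline stages."""


class ReactnormError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(ReactnormError, ValueError):
    """A caller-supplied argument violates a precondition."""


class DataError(ReactnormError):
    """Input data are structurally valid but unusable (e.g. an all-missing environment)."""


class SchemaError(ReactnormError):
    """A file or table does not match the expected schema."""


class SingularDesignError(ReactnormError):
    """A regression design with no usable variation (identical environmental means)."""


class DegenerateDesignError(ReactnormError):
    """A marker matrix without variation between genotypes."""


class CoverageError(ReactnormError):
    """A weather series does not cover the requested window."""
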