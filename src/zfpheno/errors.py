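"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (configuration, validation,
I/O) so batch callers can distinguish bad settings from bad data.
"""


class ZfphenoError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ZfphenoError):
    """A run configuration is incomplete or inconsistent."""


class FormatError(ZfphenoError):
    """An input file does not match the expected schema."""


class ValidationError(ZfphenoError):
    """Data violate a documented invariant (e.g. non-uniform sampling)."""


class DegenerateVarianceError(ValidationError):
    """Both samples of a two-sample test have zero variance."""


class UnbalancedDesignError(ValidationError):
    """A factorial design is not balanced; only balanced designs are supported."""
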