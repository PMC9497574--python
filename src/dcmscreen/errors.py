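"""Exception hierarchy shared across the package.

Every error raised by dcmscreen derives from :class:`DcmScreenError`, so
callers (and the CLI) can distinguish our failures from programming errors.
"""


class DcmScreenError(Exception):
    """Base class for all dcmscreen errors."""


class SchemaError(DcmScreenError):
    """A cohort file is missing required columns or is otherwise unreadable."""


class ValidationError(DcmScreenError):
    """A record violates a measurement invariant (units, sign, quantization)."""


class AgeRangeError(ValidationError):
    """Age falls outside the supported 40-89 year analysis window."""


class ConfigurationError(DcmScreenError):
    """Inconsistent run configuration (duplicate strata, missing cutoffs...)."""


class InsufficientDataError(DcmScreenError):
    """A computation needs cases and controls that the data do not provide."""
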