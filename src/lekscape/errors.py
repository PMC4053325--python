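"""Exception hierarchy shared across the package."""


class LekscapeError(Exception):
    """Base class for all package errors."""


class FormatError(LekscapeError):
    """A file does not conform to the expected layout (missing columns, bad header)."""


class ValidationError(LekscapeError):
    """A record violates a domain invariant (negative count, reversed interval)."""


class ConfigurationError(LekscapeError):
    """A configuration value is inconsistent with the data it is applied to."""


class ContractError(LekscapeError):
    """A caller violated an operation precondition (missing years, mismatched keys)."""


class DegenerateDesignError(LekscapeError):
    """A regression design has no usable spread (zero covariate variance, rank deficiency)."""


class UnboundedThresholdError(LekscapeError):
    """A sustainable-density query has no finite answer (non-declining response line)."""
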