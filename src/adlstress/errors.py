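"""Exception types shared across the package."""


class AdlStressError(Exception):
    """Base class for all package-specific errors."""


class DomainError(AdlStressError, ValueError):
    """A scalar input lies outside the mathematically valid domain."""


class ValidationError(AdlStressError, ValueError):
    """Structured input data violates a schema or ordering invariant."""


class ConfigError(AdlStressError, ValueError):
    """A configuration object has an invalid field.

    The message always names the offending field.
    """
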