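"""Exception types shared across the package."""


class SweetvalError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SweetvalError, ValueError):
    """A statistic or operation was handed data it cannot compute on."""


class ConfigurationError(SweetvalError, ValueError):
    """A configuration table or option is missing or inconsistent."""
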