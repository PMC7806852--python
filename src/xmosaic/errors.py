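"""Exception types shared across the package."""


class XmosaicError(Exception):
    """Base class for all package errors."""


class ConfigurationError(XmosaicError, ValueError):
    """Invalid parameter or region configuration."""


class InputError(XmosaicError, ValueError):
    """Malformed, misaligned or empty input data."""
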