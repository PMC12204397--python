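"""Exception hierarchy shared across the package."""


class TaxodelimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TaxodelimError, ValueError):
    """A configuration field is missing, out of range, or inconsistent."""


class InputError(TaxodelimError, ValueError):
    """An input table or argument violates a documented contract."""
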