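"""Exception hierarchy shared across the package."""


class RGESError(Exception):
    """Base class for all package-specific errors."""


class DataError(RGESError):
    """Malformed, inconsistent, or insufficient input data."""
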