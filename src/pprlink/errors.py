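"""Exception types shared across the package."""


class PprlinkError(Exception):
    """Base class for all package errors."""


class DataError(PprlinkError):
    """Invalid or inconsistent input data (bad file, duplicate ID, length mismatch)."""


class ConfigError(PprlinkError):
    """Invalid configuration (missing secret, bad parameter set, unknown scheme)."""
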