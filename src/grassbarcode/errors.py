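"""Exception hierarchy shared across the pipeline stages."""


class GrassBarcodeError(Exception):
    """Base class for all package errors."""


class DataValidationError(GrassBarcodeError, ValueError):
    """Malformed or inconsistent input data (bad characters, missing records...)."""


class ComputationError(GrassBarcodeError, RuntimeError):
    """A computation cannot proceed (e.g. saturated distances fed to NJ)."""
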