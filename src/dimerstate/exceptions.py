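"""Exception hierarchy shared across the package."""


class DimerstateError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DimerstateError):
    """A simulation or run configuration is invalid."""


class CalibrationError(DimerstateError):
    """Correction-factor estimation cannot proceed (too few bursts, no spread...)."""


class FitError(DimerstateError):
    """A model fit failed to converge or is underdetermined."""


class DataFormatError(DimerstateError):
    """An input file violates the expected on-disk format."""
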