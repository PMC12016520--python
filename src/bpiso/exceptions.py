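"""Exception hierarchy for the biphytane isotope pipeline."""


class BpisoError(Exception):
    """Base class for all package errors."""


class ConfigError(BpisoError):
    """Invalid configuration (non-positive sigma, bad ranges, ...)."""


class SchemaError(BpisoError):
    """A delimited input file does not match the documented schema."""


class CalibrationError(BpisoError):
    """Standards regression cannot be fitted or inverted."""


class FittingError(BpisoError):
    """A growth-curve or regression fit failed (too few points, bad data)."""


class MassBalanceError(BpisoError):
    """Isotope mass balance is unidentifiable for the supplied endmembers."""
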