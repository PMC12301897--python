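"""Exception hierarchy shared across the package."""


class EegAgeError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(EegAgeError, ValueError):
    """Invalid configuration value."""


class FormatError(EegAgeError, ValueError):
    """Malformed file (e.g. broken EDF)."""


class MontageError(EegAgeError, ValueError):
    """Channel labels missing from, or unmappable to, the requested montage."""


class TooShortError(EegAgeError, ValueError):
    """Recording shorter than an operation requires."""

class DegenerateDataError(EegAgeError, ValueError):
    """Data degenerate for the requested fit (zero variance, rank deficiency)."""


class LeakageError(EegAgeError, ValueError):
    """Subject overlap between splits that must be disjoint."""


class ClassError(EegAgeError, ValueError):
    """An operation requiring both classes received only one."""


class PatternError(EegAgeError, ValueError):
    """Label sequence does not match the required transition pattern."""
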