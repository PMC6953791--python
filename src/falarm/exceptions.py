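"""Exception hierarchy.

All package-specific failures derive from :class:`FalarmError` so callers can
catch one base class; I/O failures use the builtin ``OSError`` family.
"""


class FalarmError(Exception):
    """Base class for all falarm-specific errors."""


class SchemaError(FalarmError):
    """Malformed input: bad header, bad label table, non-distribution vector."""


class UnsupportedRateError(SchemaError):
    """Record sampled at a rate other than 250 Hz (resampling is out of scope)."""


class MissingModalityError(FalarmError):
    """A requested channel role (ECG_II / ABP / PPG) is absent from a record."""


class InsufficientDataError(FalarmError):
    """Not enough samples to fill the analysis window or a segment."""


class ShapeError(FalarmError):
    """Array dimensions inconsistent with the configured architecture."""


class ConfigError(FalarmError):
    """Invalid experiment configuration (e.g. more folds than records)."""


class ContractError(FalarmError):
    """An operation was invoked on an object in the wrong state
    (e.g. class probabilities requested from a softmax-stripped network)."""


class ExcludedClassError(FalarmError):
    """A per-class statistic was requested for a class with no samples."""
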