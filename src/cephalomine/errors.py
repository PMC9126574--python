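"""Exception hierarchy.

All package errors derive from :class:`CephalomineError` so callers can
catch everything with one clause; the CLI maps subfamilies to exit codes
(schema 2, undefined statistic 3, I/O 4).
"""


class CephalomineError(Exception):
    """Base class for all errors raised by cephalomine."""


class ConfigError(CephalomineError, ValueError):
    """Invalid configuration (out-of-range proportion, nonpositive SD, ...)."""


class SchemaError(CephalomineError, ValueError):
    """A table is missing required columns or has unexpected ones."""


class ParseError(SchemaError):
    """A cell could not be parsed; the message names the row and column."""


class StatisticError(CephalomineError, ValueError):
    """A requested statistic is undefined for the given input."""


class CollinearityError(StatisticError):
    """The regression design matrix is rank deficient."""


class StratumError(CephalomineError, LookupError):
    """A subject maps to no stratum, or a stratum is too small."""
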