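"""Exception hierarchy shared across the pipeline stages.

CLI exit codes map ``ConfigError`` to 2 and every other ``CardionetError``
to 1, mirroring the usual config-vs-data error split of shell tools.
"""


class CardionetError(Exception):
    """Base class for all package errors."""


class ConfigError(CardionetError, ValueError):
    """Invalid configuration value; the message names the offending field."""


class DataError(CardionetError, ValueError):
    """Input data violates a stage precondition (e.g. non-positive reference)."""


class ParseError(DataError):
    """Malformed input file; the message carries the file and line number."""


class FitError(CardionetError, ValueError):
    """Too few usable points for a log-log regression."""


class GenerationError(CardionetError, RuntimeError):
    """Synthetic-data generation could not satisfy a planted-structure
    constraint within the bounded number of retries."""
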