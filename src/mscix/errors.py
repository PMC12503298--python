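"""Typed exceptions used across the pipeline.

``ConfigError`` maps to CLI exit code 2, ``FormatError`` to exit code 3.
"""


class MscixError(Exception):
    """Base class for all package errors."""


class ConfigError(MscixError):
    """Invalid configuration: bad parameter values, missing inputs, bad stage maps."""


class FormatError(MscixError):
    """Invalid data file: wrong dimensions, unknown enum values, negative counts.

    Readers reject rather than coerce; the message names the offending record.
    """
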