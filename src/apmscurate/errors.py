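"""Exception hierarchy shared across the pipeline.

Configuration problems (bad parameters, impossible designs) and data
problems (malformed files, out-of-range values) are kept distinct so the
command line can exit with different codes for each.
"""


class APMSCurateError(Exception):
    """Base class for all package errors."""


class ConfigurationError(APMSCurateError):
    """A parameter, design or run configuration is invalid."""


class DataFormatError(APMSCurateError):
    """An input file is malformed or contains out-of-range values."""
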