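"""Exception hierarchy for pupilpipe."""


class PupilPipeError(Exception):
    """Base class for all pupilpipe errors."""


class ConfigurationError(PupilPipeError):
    """Invalid simulation or analysis configuration."""


class GenerationError(PupilPipeError):
    """Synthetic-trace parameters produced a physically implausible signal."""


class SchemaError(PupilPipeError):
    """An input file does not match the expected column/row schema."""


class CoverageError(PupilPipeError):
    """A sample series does not cover the requested epoch window."""


class RateError(PupilPipeError):
    """A series is not at the sampling rate an operation requires."""


class InsufficientDataError(PupilPipeError):
    """Too few observations for the requested statistical procedure."""
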