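"""Exception hierarchy shared across the pipeline stages."""


class CalscreenError(Exception):
    """Base class for all errors raised by calscreen."""


class FormatError(CalscreenError):
    """A file does not have the expected structure (missing column, bad role...)."""


class ParseError(CalscreenError):
    """A value inside an otherwise well-formed file could not be parsed."""


class DataError(CalscreenError):
    """Structurally valid input that violates a data contract."""


class PairingError(CalscreenError):
    """A/B duplicate plates could not be paired."""


class ParameterError(CalscreenError):
    """An argument is outside its valid domain."""


class ProfilingError(CalscreenError):
    """A trace cannot be profiled (too short, injection outside span...)."""


class QCError(CalscreenError):
    """Duplicate-consistency or artifact QC could not be computed."""


class AnalysisError(CalscreenError):
    """Profile-comparison analysis received degenerate input."""
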