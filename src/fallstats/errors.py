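"""Exception hierarchy shared across the package."""


class FallstatsError(Exception):
    """Base class for all package-specific errors."""


class CatalogueError(FallstatsError):
    """Malformed or invalid dataset-catalogue content."""


class UnknownActivityError(FallstatsError):
    """An activity label not covered by the label map."""


class TraceParseError(FallstatsError):
    """A trace file that cannot be parsed into a valid recording."""


class TraceValidationError(FallstatsError):
    """A trace object violating its structural invariants."""


class WindowTooShortError(FallstatsError):
    """Window duration and sampling rate give fewer than two samples."""


class TraceTooShortError(FallstatsError):
    """Trace shorter than the requested observation window."""


class ConfigError(FallstatsError):
    """Invalid generator, scenario, or pipeline configuration."""


class NoEligibleTracesError(FallstatsError):
    """A pipeline selection/filter left no traces to analyse."""
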