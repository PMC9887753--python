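"""Exception hierarchy for catrace."""


class CatraceError(Exception):
    """Base class for all catrace errors."""


class ConfigError(CatraceError):
    """Invalid configuration; the message names the offending field."""


class GeometryError(CatraceError):
    """ROI/frame geometry violation (overlap, out of bounds, empty region)."""


class TraceFormatError(CatraceError):
    """Malformed trace file or trace array."""


class ProtocolError(CatraceError):
    """Protocol descriptor inconsistent with the recording."""


class CaffeineNotFoundError(ProtocolError):
    """No caffeine transient detected where the protocol expects one."""


class FitError(CatraceError):
    """Decay-fit precondition violated (too few points, unconverged input)."""


class StatsError(CatraceError):
    """Statistical-test precondition violated (n too small, degenerate data)."""
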