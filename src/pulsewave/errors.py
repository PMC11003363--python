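"""Exception types raised by the pulsewave pipeline."""


class PulsewaveError(Exception):
    """Base class for all pulsewave errors."""


class ConfigError(PulsewaveError):
    """Invalid or missing configuration (e.g. no sampling rate for a raw text file)."""


class ParseError(PulsewaveError):
    """Input file content could not be parsed as numeric samples."""


class ChannelNotFoundError(PulsewaveError, KeyError):
    """Requested channel/variable does not exist in the container file."""


class FilterDesignError(PulsewaveError):
    """Filter specification is infeasible for the given sampling rate."""


class ShortSignalError(PulsewaveError):
    """Signal too short for the requested filter's warm-up/padding."""
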