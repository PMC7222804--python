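"""Exception types shared across the package."""


class MtcpgError(Exception):
    """Base class for all package errors."""


class InputFormatError(MtcpgError, ValueError):
    """A sequence or annotation file could not be parsed."""


class CoordinateError(MtcpgError, ValueError):
    """An interval or feature lies outside the genome, or is malformed."""


class ParameterError(MtcpgError, ValueError):
    """Scan, seek or synthesis parameters are invalid or infeasible."""
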