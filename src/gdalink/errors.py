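"""Exception hierarchy for the gdalink pipeline."""


class GdaLinkError(Exception):
    """Base class for all gdalink errors."""


class ParseError(GdaLinkError, ValueError):
    """A delimited edge-list file could not be parsed (names file/line)."""


class ValidationError(GdaLinkError, ValueError):
    """Input data violates a domain invariant (weights, partitions, ...)."""


class ConvergenceError(GdaLinkError, RuntimeError):
    """Training produced a non-finite loss and was aborted."""
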