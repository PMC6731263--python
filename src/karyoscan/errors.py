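"""Exception types shared across the package."""


class KaryoscanError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(KaryoscanError, ValueError):
    """A configuration or parameter value is invalid or unachievable."""


class PileupParseError(KaryoscanError, ValueError):
    """A pileup row could not be parsed; carries the offending line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


class UnsortedInputError(KaryoscanError, ValueError):
    """Input rows were not sorted by chromosome and position."""
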