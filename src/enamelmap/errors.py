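"""Named exception types used across the pipeline."""


class EnamelMapError(Exception):
    """Base class for all package errors."""


class ValidationError(EnamelMapError):
    """A configuration or input value violates a documented invariant."""


class FormatError(EnamelMapError):
    """A file could not be parsed; carries offending line numbers where known.

    Attributes
    ----------
    lines : list of (line number, message) pairs for the offending rows.
    """

    def __init__(self, message, lines=None):
        super().__init__(message)
        self.lines = list(lines or [])
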