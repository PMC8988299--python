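"""Exception hierarchy shared across the package."""


class SpindlescoreError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SpindlescoreError, ValueError):
    """A parameter violates its documented precondition."""


class DegenerateDistributionError(SpindlescoreError, ValueError):
    """A 1-D sample has no spread to threshold (all values identical)."""


class CorruptFileError(SpindlescoreError, OSError):
    """A flat-binary LFP file is inconsistent with its declared layout."""


class FormatError(SpindlescoreError, ValueError):
    """A text input file does not match any accepted dialect."""


class AlignmentError(SpindlescoreError, ValueError):
    """Input traces do not share a common time base."""
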