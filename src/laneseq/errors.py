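"""Exception hierarchy shared across laneseq modules."""


class LaneseqError(Exception):
    """Base class for all laneseq errors."""


class ValidationError(LaneseqError):
    """Input data violates an invariant (negative count, label mismatch, ...)."""


class FormatError(LaneseqError):
    """A file does not conform to the expected delimited/annotation format."""


class AnnotationError(LaneseqError):
    """Gene/transcript annotation is internally inconsistent."""
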