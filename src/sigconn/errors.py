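"""Exception hierarchy for sigconn.

Every failure mode the pipeline can hit deliberately (bad file, broken
invariant, undefined statistic) raises a subclass of :class:`SigconnError`,
so callers can catch the package's errors without swallowing bugs.
"""


class SigconnError(Exception):
    """Base class for all sigconn errors."""


class FormatError(SigconnError):
    """A file does not conform to its declared text format."""


class ValidationError(SigconnError):
    """An in-memory object violates a domain invariant."""


class AlignmentError(SigconnError):
    """Two artifacts that must share identifiers do not align."""


class ParameterError(SigconnError):
    """A caller-supplied parameter is outside its legal range."""


class EmptyQueryError(SigconnError):
    """A query signature ended up with no genes; scoring is undefined."""


class UndefinedScoreError(SigconnError):
    """A connectivity score is mathematically undefined for this input."""


class PipelineError(SigconnError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
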