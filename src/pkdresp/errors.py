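"""Exception hierarchy shared across the package."""


class PKDRespError(Exception):
    """Base class for all package errors."""


class ValidationError(PKDRespError, ValueError):
    """An input value violates a documented precondition; names the offending field."""


class MissingDataError(PKDRespError):
    """A required measurement is absent (e.g. no sequence covering both kidneys)."""


class InsufficientDataError(PKDRespError):
    """Too few observations for the requested fit (e.g. <2 distinct scan ages)."""


class EligibilityError(PKDRespError):
    """A treatment window does not satisfy the study's scan requirements."""


class DegenerateInputError(PKDRespError):
    """Input admits no meaningful answer (e.g. clustering identical values)."""


class AmbiguityError(PKDRespError):
    """A decision rule cannot break a tie (e.g. equal cluster means)."""


class PipelineError(PKDRespError):
    """A pipeline stage failed; carries the stage name and a short code."""

    def __init__(self, stage: str, code: str, message: str = ""):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}] {code}" + (f": {message}" if message else ""))
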