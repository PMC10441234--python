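"""Exception hierarchy shared across the pipeline."""


class MeripChipError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(MeripChipError):
    """A value or object violates a documented invariant."""


class FormatError(MeripChipError):
    """An input file or table is malformed."""


class AlignmentError(MeripChipError):
    """Two tables that must share an index do not."""


class StageError(MeripChipError):
    """A pipeline stage failed; carries the stage name for reporting."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
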