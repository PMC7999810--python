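"""Exception hierarchy shared across the pipeline."""


class InfarctSegError(Exception):
    """Base class for all package errors."""


class InputError(InfarctSegError):
    """Invalid or unreadable input data (NaNs, missing files, empty sets)."""


class ShapeError(InfarctSegError):
    """Array rank or dimension mismatch."""


class ParameterError(InfarctSegError):
    """Invalid configuration or hyperparameter value."""


class ValidationError(InfarctSegError):
    """A domain-type invariant was violated."""


class DependencyError(InfarctSegError):
    """A requested external backend/tool is unavailable."""


class ConsistencyError(InfarctSegError):
    """Internal bookkeeping mismatch (e.g. unknown patch reference ID)."""


class UndefinedMeasureError(InfarctSegError):
    """An evaluation measure is undefined for the given masks."""


class PlacementError(InfarctSegError):
    """Phantom lesions could not be placed within the retry budget."""


class StageError(InfarctSegError):
    """A pipeline stage failed; carries the stage name and subject ID."""

    def __init__(self, stage: str, subject_id: str | None, cause: Exception):
        self.stage = stage
        self.subject_id = subject_id
        self.cause = cause
        where = f" (subject {subject_id})" if subject_id else ""
        super().__init__(f"stage '{stage}'{where} failed: {cause}")
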