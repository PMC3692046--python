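"""Exception hierarchy shared across tmakit modules."""


class TmakitError(Exception):
    """Base class for all tmakit errors."""


class GridFormatError(TmakitError):
    """A score grid could not be parsed (bad dialect, non-numeric cell, ...)."""


class ValidationError(TmakitError):
    """Parsed data violates a structural requirement (duplicate IDs, missing batch labels, ...)."""


class DegenerateDataError(TmakitError):
    """Input is too small or too uniform for the requested computation."""


class ConvergenceError(TmakitError):
    """An iterative fit failed to converge within its iteration budget."""
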