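"""Exception types shared across the package."""


class FCReconfError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FCReconfError, ValueError):
    """A delimited file is missing required columns or is otherwise malformed."""


class DuplicateEntryError(FormatError):
    """A manifest lists the same (subject, state) twice."""


class ParseError(FCReconfError, ValueError):
    """A cell that should be numeric could not be parsed, or is non-finite."""


class ShapeError(FCReconfError, ValueError):
    """An array has the wrong number of rows/columns for the operation."""


class DegenerateInputError(FCReconfError, ValueError):
    """An input has zero variance where variance is required (names the culprit)."""


class PairingError(FCReconfError, ValueError):
    """Two per-subject objects that must belong to the same subject do not."""


class ConsistencyError(FCReconfError, ValueError):
    """An internal invariant (e.g. matrix symmetry) is violated beyond tolerance."""


class CollinearityError(FCReconfError, ValueError):
    """A covariate design matrix is rank deficient after adding the intercept."""


class CalibrationError(FCReconfError, ValueError):
    """A planted target is unreachable; carries the feasible noise floor."""

    def __init__(self, message: str, floor: float | None = None):
        super().__init__(message)
        self.floor = floor


class PipelineStageError(FCReconfError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
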