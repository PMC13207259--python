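"""Exception hierarchy shared across the toolkit."""


class TedClaimsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TedClaimsError):
    """A configuration value is out of its admissible range or inconsistent."""


class InputError(TedClaimsError):
    """Malformed caller input (bad vectors, unsorted spans, length mismatch...)."""


class ParseError(TedClaimsError):
    """A data file could not be parsed; carries the offending row when known."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class InfeasibleReferenceError(ConfigurationError):
    """Requested reference-standard precision cannot be reached at the given
    prevalence and recall; carries the implied false-positive rate."""

    def __init__(self, implied_fp_rate: float, message: str | None = None):
        self.implied_fp_rate = implied_fp_rate
        super().__init__(
            message
            or "requested precision infeasible: implied false-positive "
            f"probability {implied_fp_rate:.4f} outside [0, 1]"
        )


class LeakageError(TedClaimsError):
    """Train and test patient sets overlap."""


class StageError(TedClaimsError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.__cause__ = cause
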