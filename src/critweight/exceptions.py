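"""Exception and warning hierarchy for the critweight pipeline."""


class CritweightError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(CritweightError):
    """A declared input column is missing or the schema is unusable."""


class RowParseError(CritweightError):
    """A row of an input table failed validation; carries the row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class InvariantError(CritweightError):
    """A domain-type invariant is violated (e.g. reversed CI bounds)."""


class DegenerateDesignError(CritweightError):
    """The regression design is rank deficient (e.g. a single age class)."""


class NoBreakpointError(CritweightError):
    """No interior breakpoint candidate has enough data on both sides."""


class UnstableEstimateError(CritweightError):
    """Too many resampling replicates failed to fit (> 20 %)."""


class ConfigError(CritweightError):
    """A synthetic-cohort configuration is invalid or biologically impossible."""


class DegenerateFitWarning(UserWarning):
    """The RSS profile is flat at its minimum; tie broken to the smallest age."""


class ExtrapolationWarning(UserWarning):
    """A growth-curve prediction fell outside the plausible feeding range."""


class EstimateWarning(UserWarning):
    """A point estimate fell outside its own bootstrap interval."""
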