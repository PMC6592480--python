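"""Exception hierarchy for the aeemax pipeline."""


class AeemaxError(Exception):
    """Base class for all package errors."""


class FormatError(AeemaxError):
    """A file does not conform to the expected layout (columns, tokens, duplicates)."""


class DataError(AeemaxError):
    """Contents are well-formed but violate a data contract (ordering, lengths, missing covariates)."""


class ParameterError(AeemaxError, ValueError):
    """An argument is outside its allowed domain (even window, nonpositive age, ...)."""


class InsufficientDataError(DataError):
    """Too little usable data to compute a quantity.

    Carries ``n_points`` (what was available) and ``required`` so batch
    drivers can report exclusions without string parsing.
    """

    def __init__(self, message: str, n_points: int | None = None,
                 required: int | None = None, subject_id: str | None = None):
        super().__init__(message)
        self.n_points = n_points
        self.required = required
        self.subject_id = subject_id


class DegenerateFitError(DataError):
    """A regression cannot be fit (zero predictor variance, rank-deficient design, unit leverage)."""
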