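"""Exception hierarchy shared across the package."""


class FertisimError(Exception):
    """Base class for all package-specific errors."""


class CoverageError(FertisimError):
    """A macro-indicator series does not cover the years a computation needs."""


class ConfigError(FertisimError):
    """An invalid generator or pipeline configuration."""


class ValidationError(FertisimError):
    """Life-course or person-year data violating a structural invariant."""


class ModelSpecError(FertisimError):
    """An unknown or malformed hazard-model specification."""


class RankDeficiencyError(FertisimError):
    """A design matrix with linearly dependent columns.

    ``columns`` names the offending columns (those that a pivoted QR
    factorisation places beyond the numerical rank).
    """

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


class DataError(FertisimError):
    """Degenerate data that makes an estimator undefined (e.g. no events)."""
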