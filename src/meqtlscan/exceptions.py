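"""Exception hierarchy shared across the package."""


class MeqtlScanError(Exception):
    """Base class for package errors."""


class ConfigurationError(MeqtlScanError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class DomainError(MeqtlScanError, ValueError):
    """A numeric input is outside the mathematical domain of an operation."""


class DimensionError(MeqtlScanError, ValueError):
    """Matrices or tables that must be aligned are not."""


class CollinearityError(MeqtlScanError, ValueError):
    """A regression design matrix is rank deficient.

    Carries the names of the offending columns.
    """

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: {self.columns}")
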