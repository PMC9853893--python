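"""Exception hierarchy shared by all pipeline stages."""


class GmprogError(Exception):
    """Base class for all errors raised by this package."""


class SpecValidationError(GmprogError, ValueError):
    """A cohort spec or pipeline config field is invalid.

    Carries the offending field name in ``field``.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class ShapeError(GmprogError, ValueError):
    """Grids or vectors that must be aligned have different shapes."""


class VolumeValidationError(GmprogError, ValueError):
    """A volume violates its invariants (non-finite or negative values)."""


class ReconciliationError(GmprogError, ValueError):
    """Volume files and phenotype rows do not match one-to-one."""

    def __init__(self, message: str, offenders=()):
        self.offenders = list(offenders)
        super().__init__(message)


class DegenerateInputError(GmprogError, ValueError):
    """Input is degenerate for the requested operation (e.g. empty mask)."""


class InsufficientDataError(GmprogError, ValueError):
    """Too few observations for the requested statistic."""


class PairingError(GmprogError, ValueError):
    """Longitudinal pairing between timepoints is broken."""

    def __init__(self, message: str, subjects=()):
        self.subjects = list(subjects)
        super().__init__(message)


class CollinearityError(GmprogError, ValueError):
    """Regressors are (near-)collinear; the coefficient is not identified."""


class ConstructionError(GmprogError, ValueError):
    """A derived table (e.g. the feature matrix) cannot be assembled."""
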