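"""Exception hierarchy shared by all pipeline stages."""


class PneumoriskError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(PneumoriskError, ValueError):
    """An argument violates a documented precondition."""


class CalibrationError(PneumoriskError):
    """Intercept calibration produced an unusable linear predictor."""


class ConvergenceError(PneumoriskError):
    """IRLS failed to converge; carries the last iterate in ``last_result``."""

    def __init__(self, message, last_result=None):
        super().__init__(message)
        self.last_result = last_result


class RankDeficiencyError(PneumoriskError):
    """Design matrix has fewer rows than columns or is rank deficient."""


class AllCollinearError(PneumoriskError):
    """Backward elimination would leave fewer than one predictor."""


class DegenerateInputError(PneumoriskError):
    """Input is formally valid but statistically degenerate (e.g. one-sign residuals)."""


class SchemaError(PneumoriskError):
    """A tabular file is missing a required column."""


class TableParseError(PneumoriskError):
    """A cell value cannot be parsed; carries the offending 1-based data row."""

    def __init__(self, message, row=None):
        super().__init__(message)
        self.row = row


class FormatError(PneumoriskError):
    """A raster/GeoJSON file does not match the expected on-disk layout."""


class EmptyZoneError(PneumoriskError):
    """A polygon contains no raster cell centers; carries the district id."""

    def __init__(self, message, district_id=None):
        super().__init__(message)
        self.district_id = district_id


class UndefinedGVFError(PneumoriskError):
    """Goodness-of-variance fit is undefined (zero total deviation)."""


class PipelineStageError(PneumoriskError):
    """A pipeline stage failed; carries the stage name and the original error."""

    def __init__(self, stage, original):
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
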