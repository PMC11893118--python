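"""Exception hierarchy shared across cropclock modules."""


class CropClockError(Exception):
    """Base class for all cropclock errors."""


class ArgumentError(CropClockError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(CropClockError):
    """A file does not conform to the expected CSV dialect."""


class ValidationError(CropClockError):
    """Parsed data violates a domain invariant (e.g. tmin > tmax)."""


class CoverageError(CropClockError):
    """A requested date window is not fully covered by a weather series."""

    def __init__(self, message: str, missing_dates=None):
        super().__init__(message)
        self.missing_dates = list(missing_dates) if missing_dates is not None else []


class MissingDataError(CropClockError):
    """An optional weather variable is absent for part of a window."""


class ConcordanceError(CropClockError):
    """Crop records could not be matched to weather series."""

    def __init__(self, message: str, record_ids=None):
        super().__init__(message)
        self.record_ids = list(record_ids) if record_ids is not None else []


class FitError(CropClockError):
    """A model fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class ScanError(CropClockError):
    """A sowing-date scan produced no valid rows."""
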