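"""Exception hierarchy for the carrionball pipeline.

Every stage raises a subclass of :class:`CarrionballError` so callers can
catch pipeline failures without masking programming errors.
"""


class CarrionballError(Exception):
    """Base class for all carrionball errors."""


class InvalidInputError(CarrionballError):
    """An input image, mask or measure violates a precondition."""


class InvalidParameterError(CarrionballError):
    """A tuning parameter is out of its valid range (e.g. even filter size)."""


class DegenerateHistogramError(CarrionballError):
    """Thresholding was asked to split a constant-intensity image."""


class NoObjectError(CarrionballError):
    """A mask that should contain a foreground object is empty."""


class ContractViolationError(CarrionballError):
    """An intermediate result violates a stage contract (e.g. multiple
    components reaching ``measure``)."""


class CalibrationError(CarrionballError):
    """The synthetic blob generator could not reach the requested target
    roundness within its iteration budget."""


class DegenerateInputError(CarrionballError):
    """A statistical routine received constant or too-small input."""


class CollinearityError(CarrionballError):
    """The design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; offending columns: "
            + ", ".join(self.columns)
        )


class InsufficientGroupError(CarrionballError):
    """A variance-comparison group has fewer than two rows."""


class SchemaError(CarrionballError):
    """A table is missing required columns."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__("missing required columns: " + ", ".join(self.missing))
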