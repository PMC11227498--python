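"""Exception hierarchy for ihcsub.

Each validation failure raises a distinct, named error so callers can
react to (and tests can assert on) the precise failure mode.
"""


class IhcsubError(Exception):
    """Base class for all ihcsub errors."""


class MissingFileError(IhcsubError):
    """Input file does not exist."""


class SchemaError(IhcsubError):
    """Input file header/shape does not match the documented schema."""


class DuplicateCaseIdError(IhcsubError):
    """Two rows share the same case_id."""


class FieldRangeError(IhcsubError):
    """A numeric field is outside its documented range.

    Carries the offending row identifier and field name.
    """

    def __init__(self, message: str, *, row: object = None, field: str | None = None):
        super().__init__(message)
        self.row = row
        self.field = field


class InconsistentStainError(FieldRangeError):
    """Intensity and proportion violate the zero-pair consistency rule."""


class UnknownTokenError(IhcsubError):
    """A categorical field holds a token outside its documented vocabulary."""


class DegenerateTableError(IhcsubError):
    """A cross-tabulation factor has fewer than two observed levels."""


class DegenerateClusteringError(IhcsubError):
    """Clustering input carries no structure usable for pattern labeling."""


class TransformStateError(IhcsubError):
    """An expression-matrix operation was applied in the wrong transform state."""


class MissingGeneError(IhcsubError):
    """A required signature gene is absent from the expression matrix."""


class ConfigError(IhcsubError):
    """A simulation or run configuration is invalid."""
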