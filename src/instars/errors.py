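"""Exception hierarchy shared across the package."""


class InstarsError(Exception):
    """Base class for all package errors."""


class ValidationError(InstarsError):
    """An input value or table violates a documented invariant."""


class FormatError(ValidationError):
    """A file is structurally malformed (e.g. a required CSV column is missing)."""


class EmptyInputError(ValidationError):
    """A file or table contains no usable records."""


class ConfigError(ValidationError):
    """A generator or inference configuration is internally inconsistent."""


class InsufficientDataError(InstarsError):
    """Too few observations for the requested operation."""


class DegenerateDataError(InstarsError):
    """The data cannot support the requested model (e.g. K exceeds distinct values)."""


class AnchoringConflictError(InstarsError):
    """Every candidate instar number conflicts with the embryo/prepupa anchors."""


class VocabularyError(InstarsError):
    """A qualitative observation uses a character or value outside the key's vocabulary."""


class DiagnosabilityError(InstarsError):
    """A specimen shares no measured character with the reference summaries."""
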