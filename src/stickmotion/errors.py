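"""Exception hierarchy shared across the package.

Three failure classes are distinguished so that callers (and the CLI exit
codes) can react differently to malformed files, semantically invalid data,
and bad parameter values.
"""


class StickmotionError(Exception):
    """Base class for all package-specific errors."""


class InputFormatError(StickmotionError):
    """A file or table does not conform to the expected layout.

    Raised for missing columns, duplicated keys, values that fail to parse,
    or frame indices that violate the declared sampling grid.
    """


class DataValidationError(StickmotionError):
    """Structurally valid input that is semantically unusable.

    Examples: a landmark absent from a frame that an operation needs, an
    incomplete rating matrix passed to a reliability estimate, or too few
    stimuli for an extreme-group split.
    """


class ParameterError(StickmotionError):
    """An argument is outside its documented domain (e.g. negative stride)."""
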