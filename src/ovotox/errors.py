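"""Structured errors with machine-readable codes.

Every error raised by a pipeline stage carries a short ``code`` so the CLI
can abort with the stage name and a stable identifier (exit status 2).
"""


class OvotoxError(Exception):
    """Base class for all package errors."""

    code = "E_GENERIC"

    def __init__(self, message: str, code: str | None = None):
        super().__init__(message)
        if code is not None:
            self.code = code


class ValidationError(OvotoxError):
    """An input object violates a documented invariant."""

    code = "E_VALIDATION"


class ParseError(OvotoxError):
    """A file could not be parsed; message names the file and location."""

    code = "E_PARSE"


class MetadataError(ValidationError):
    """Sample/cell metadata is missing columns or inconsistent."""

    code = "E_META"


class PlateError(ValidationError):
    """A statistical contrast would cross sequencing plates."""

    code = "E_PLATE"


class EmptyAtlasError(OvotoxError):
    """Cell QC removed every cell."""

    code = "E_EMPTY_ATLAS"


class UnderdeterminedError(OvotoxError):
    """Too few genes survive ortholog/variable-gene restriction."""

    code = "E_UNDERDETERMINED"
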