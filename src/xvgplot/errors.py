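"""Exception hierarchy shared across the package."""


class XvgplotError(Exception):
    """Base class for all package errors."""


class ParseError(XvgplotError):
    """A file could not be parsed; message carries the file and line number."""

    def __init__(self, message: str, path=None, line_number: int | None = None):
        self.path = str(path) if path is not None else None
        self.line_number = line_number
        prefix = ""
        if self.path is not None:
            prefix = self.path
            if line_number is not None:
                prefix += f":{line_number}"
            prefix += ": "
        super().__init__(prefix + message)


class EmptyDocumentError(ParseError):
    """File contained no data rows."""


class FormatError(ParseError):
    """File structure is undecidable (e.g. no delimiter yields two columns)."""


class OptionError(XvgplotError):
    """Invalid or conflicting user options."""


class UsageError(XvgplotError):
    """Bad command-line invocation."""


class EstimationError(XvgplotError):
    """A statistical estimate cannot be computed from the given data."""
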