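"""Exception hierarchy shared across the pipeline."""


class TcqeError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(TcqeError):
    """An input table does not conform to its declared schema."""


class ParseError(TcqeError):
    """A cell value could not be coerced to the schema type."""


class GmtFormatError(TcqeError):
    """A GMT line is malformed (fewer than three fields, or no members)."""


class ValidationError(TcqeError):
    """A value violates a domain invariant (e.g. probability outside [0, 1])."""


class AssayError(TcqeError):
    """A bioassay is invalid or cannot be evaluated (bad controls, g >= 1, ...)."""
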