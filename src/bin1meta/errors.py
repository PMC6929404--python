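"""Exception hierarchy shared by all bin1meta modules."""


class Bin1MetaError(Exception):
    """Base class for all package errors."""


class SchemaError(Bin1MetaError):
    """A required column is missing or the file layout is unusable."""


class ValidationError(Bin1MetaError):
    """A cell or record violates a domain invariant; carries row context."""

    def __init__(self, message: str, row: int | None = None, label: str | None = None):
        self.row = row
        self.label = label
        ctx = []
        if row is not None:
            ctx.append(f"row {row}")
        if label:
            ctx.append(f"study {label!r}")
        super().__init__(f"{message}" + (f" ({', '.join(ctx)})" if ctx else ""))


class DegenerateTableError(Bin1MetaError):
    """A 2x2 table has an empty arm or undefined odds ratio."""


class InsufficientStudiesError(Bin1MetaError):
    """Fewer studies than the analysis requires."""


class PipelineError(Bin1MetaError):
    """A whole analysis step could not produce any output."""
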