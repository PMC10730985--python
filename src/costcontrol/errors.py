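"""Exception hierarchy for the cost-of-control pipeline."""


class CostControlError(Exception):
    """Base class for all package errors."""


class DomainError(CostControlError, ValueError):
    """An argument violates the mathematical domain of an operation."""


class SchemaError(CostControlError, ValueError):
    """An input file or record violates the expected schema.

    Carries enough context (row, field) to point the user at the
    offending record.
    """

    def __init__(self, message: str, *, row: object = None, field: str | None = None):
        parts = [message]
        if row is not None:
            parts.append(f"row={row!r}")
        if field is not None:
            parts.append(f"field={field!r}")
        super().__init__("; ".join(parts))
        self.row = row
        self.field = field


class UndefinedNNTError(DomainError):
    """Raised when ARR is zero: no patients reach target, NNT is undefined (infinite)."""
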