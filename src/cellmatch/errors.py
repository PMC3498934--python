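"""Exception hierarchy shared across the package."""


class CellMatchError(Exception):
    """Base class for all package errors."""


class DegenerateCellError(CellMatchError):
    """A unit cell violates a geometric invariant (length, angle or v^2)."""


class SingularBasisError(CellMatchError):
    """Three basis vectors are linearly dependent."""


class UnknownSpaceGroupError(CellMatchError):
    """A space-group symbol could not be resolved to a Sohncke group."""

    def __init__(self, symbol: str, candidates: list[str] | None = None):
        self.symbol = symbol
        self.candidates = candidates or []
        msg = f"unknown space group {symbol!r}"
        if self.candidates:
            msg += "; nearest symbols: " + ", ".join(self.candidates)
        super().__init__(msg)


class ReductionError(CellMatchError):
    """Niggli reduction failed to converge within the step cap."""


class IngestError(CellMatchError):
    """An input record could not be turned into a database entry."""


class DatabaseFormatError(CellMatchError):
    """A persisted database file is corrupt or has the wrong version."""
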