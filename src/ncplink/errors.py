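"""Exception hierarchy shared across the package."""

from __future__ import annotations


class NcplinkError(Exception):
    """Base class for all package-specific errors."""


class CatalogError(NcplinkError):
    """Malformed or inconsistent NCP catalog."""


class TableValidationError(NcplinkError):
    """A relationship table violates one or more invariants.

    Carries the full validation report so callers can inspect or
    serialise the individual violations.
    """

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


class CellValueError(NcplinkError):
    """A cell holds a value outside {1, 0, -1, NA}; names row and column."""

    def __init__(self, species_id: str, column: str, raw):
        self.species_id = species_id
        self.column = column
        self.raw = raw
        super().__init__(
            f"invalid cell value {raw!r} at species {species_id!r}, column {column!r}; "
            "expected one of 1, 0, -1 or empty"
        )


class MergeConflictError(NcplinkError):
    """Conflicting non-NA values met while merging synonym rows."""


class UnknownSpeciesError(NcplinkError, LookupError):
    """Species id(s) absent from the relationship table."""

    def __init__(self, species_ids):
        self.species_ids = sorted(species_ids)
        super().__init__(f"unknown species id(s): {', '.join(self.species_ids)}")


class UnknownNCPError(NcplinkError, LookupError):
    """NCP id absent from the catalog."""
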