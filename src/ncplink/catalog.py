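"""NCP catalog: identity, category, lineage applicability and sign permissions.

The catalog is a small, ordered collection of NCP (Nature's Contributions to
People) definitions.  A built-in 17-entry catalog covering two lineages
(tracheophytes and vertebrates) ships with the package and can be loaded with
``load_catalog("builtin")``; user catalogs are flat CSV files with the same
schema (see :func:`write_catalog`).
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import CatalogError, UnknownNCPError

#: Recognised NCP categories.
CATEGORIES = ("material", "non_material", "regulating")

#: Recognised lineage tokens.
LINEAGES = ("tracheophyte", "vertebrate")

#: Recognised evidence-source tokens (descriptive metadata only).
SOURCES = ("references", "expert", "analytics")

BUILTIN_TOKEN = "builtin"

_CSV_COLUMNS = ["ncp_id", "label", "category", "applicable_lineages",
                "negative_allowed", "sources"]


@dataclass(frozen=True)
class NCPDefinition:
    """One NCP: a stable id plus category, applicability and sign rules.

    Parameters
    ----------
    ncp_id
        Short stable token used as a join key in all tables (snake_case).
    label
        Human-readable name.
    category
        One of ``material``, ``non_material``, ``regulating``.
    applicable_lineages
        Non-empty subset of ``{"tracheophyte", "vertebrate"}``.
    negative_allowed
        Whether a ``-1`` relationship value is permitted for this NCP.
    sources
        Subset of ``{"references", "expert", "analytics"}``.  Metadata only;
        never gates computation.
    """

    ncp_id: str
    label: str
    category: str
    applicable_lineages: frozenset = field(default_factory=frozenset)
    negative_allowed: bool = True
    sources: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "applicable_lineages",
                           frozenset(self.applicable_lineages))
        object.__setattr__(self, "sources", frozenset(self.sources))
        if self.category not in CATEGORIES:
            raise CatalogError(
                f"NCP {self.ncp_id!r}: category {self.category!r} not in {CATEGORIES}")
        if not self.applicable_lineages:
            raise CatalogError(f"NCP {self.ncp_id!r}: applicable_lineages is empty")
        unknown = self.applicable_lineages - set(LINEAGES)
        if unknown:
            raise CatalogError(
                f"NCP {self.ncp_id!r}: unknown lineage token(s) {sorted(unknown)}")
        unknown_src = self.sources - set(SOURCES)
        if unknown_src:
            raise CatalogError(
                f"NCP {self.ncp_id!r}: unknown source token(s) {sorted(unknown_src)}")
        if self.category == "non_material" and self.negative_allowed:
            raise CatalogError(
                f"NCP {self.ncp_id!r}: non-material NCPs cannot allow negative values")

    def applies_to(self, lineage: str) -> bool:
        return lineage in self.applicable_lineages


class NCPCatalog:
    """Ordered, id-unique collection of :class:`NCPDefinition`."""

    def __init__(self, ncps: Iterable[NCPDefinition]):
        self._ncps = list(ncps)
        self._by_id = {}
        for ncp in self._ncps:
            if ncp.ncp_id in self._by_id:
                raise CatalogError(f"duplicate ncp_id {ncp.ncp_id!r}")
            self._by_id[ncp.ncp_id] = ncp

    def __len__(self) -> int:
        return len(self._ncps)

    def __iter__(self) -> Iterator[NCPDefinition]:
        return iter(self._ncps)

    def __contains__(self, ncp_id: str) -> bool:
        return ncp_id in self._by_id

    def __eq__(self, other) -> bool:
        if not isinstance(other, NCPCatalog):
            return NotImplemented
        return self._ncps == other._ncps

    def get(self, ncp_id: str) -> NCPDefinition:
        try:
            return self._by_id[ncp_id]
        except KeyError:
            raise UnknownNCPError(f"unknown ncp_id {ncp_id!r}") from None

    @property
    def ncp_ids(self) -> list:
        """Catalog-ordered list of ncp_ids."""
        return [n.ncp_id for n in self._ncps]

    def category_of(self, ncp_id: str) -> str:
        return self.get(ncp_id).category

    def category_ids(self, category: str) -> list:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
        return [n.ncp_id for n in self._ncps if n.category == category]


def applicability_mask(catalog: NCPCatalog, lineage: str) -> set:
    """Return the set of ncp_ids applicable to ``lineage``.

    Raises
    ------
    ValueError
        If ``lineage`` is not a recognised lineage token.
    """
    if lineage not in LINEAGES:
        raise ValueError(f"unknown lineage {lineage!r}; expected one of {LINEAGES}")
    return {n.ncp_id for n in catalog if n.applies_to(lineage)}


def _parse_bool(raw: str, row_label: str) -> bool:
    token = raw.strip().lower()
    if token in ("true", "1", "yes"):
        return True
    if token in ("false", "0", "no"):
        return False
    raise CatalogError(f"row {row_label}: cannot parse boolean {raw!r}")


def load_catalog(source) -> NCPCatalog:
    """Load a catalog from a CSV file, or the built-in one for ``"builtin"``.

    The built-in catalog has 17 NCPs: 16 applicable to tracheophytes, 9 to
    vertebrates, 8 to both.
    """
    if str(source) == BUILTIN_TOKEN:
        ref = importlib.resources.files("ncplink").joinpath("data/ncp_catalog.csv")
        with ref.open("r", encoding="utf-8", newline="") as fh:
            return _read_catalog_csv(fh, "builtin catalog")
    path = Path(source)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        return _read_catalog_csv(fh, str(path))


def _read_catalog_csv(fh, origin: str) -> NCPCatalog:
    reader = csv.DictReader(fh)
    if reader.fieldnames is None:
        raise CatalogError(f"{origin}: empty catalog file (no header)")
    missing = [c for c in _CSV_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise CatalogError(f"{origin}: missing column(s) {missing}")
    ncps = []
    for i, row in enumerate(reader, start=2):  # header is line 1
        label = f"{origin}:{i}"
        try:
            ncps.append(NCPDefinition(
                ncp_id=row["ncp_id"].strip(),
                label=row["label"].strip(),
                category=row["category"].strip(),
                applicable_lineages=frozenset(
                    tok.strip() for tok in row["applicable_lineages"].split(";")
                    if tok.strip()),
                negative_allowed=_parse_bool(row["negative_allowed"], label),
                sources=frozenset(
                    tok.strip() for tok in row["sources"].split(";") if tok.strip()),
            ))
        except CatalogError:
            raise
        except Exception as exc:  # malformed row: name it
            raise CatalogError(f"{label}: malformed row ({exc})") from exc
    if not ncps:
        raise CatalogError(f"{origin}: catalog contains no NCP rows")
    return NCPCatalog(ncps)


def write_catalog(catalog: NCPCatalog, path) -> None:
    """Write ``catalog`` as a flat CSV round-trippable by :func:`load_catalog`."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for ncp in catalog:
            writer.writerow([
                ncp.ncp_id,
                ncp.label,
                ncp.category,
                ";".join(sorted(ncp.applicable_lineages)),
                "true" if ncp.negative_allowed else "false",
                ";".join(sorted(ncp.sources)),
            ])
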