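"""Species x NCP relationship table: loading, validation, aggregation.

A relationship table couples species metadata with one signed value per
(species, NCP) pair.  Cell values live in {+1, 0, -1} plus two NA flavours:

* ``NA_NO_INFO`` — the NCP applies to the species' lineage but no information
  was available (stored internally as NaN inside the applicable mask);
* ``NA_NOT_APPLICABLE`` — the NCP does not apply to the lineage at all
  (never stored; derived from the catalog's applicability).

Both NA flavours contribute nothing to score sums; only ``NA_NO_INFO`` is
counted as a missing-information cell.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import CATEGORIES, LINEAGES, NCPCatalog, applicability_mask
from .errors import (CellValueError, MergeConflictError, TableValidationError,
                     UnknownNCPError, UnknownSpeciesError)

#: Subgroup tokens per lineage; used to check metadata consistency.
PLANT_SUBGROUPS = ("angiosperm", "pinophyte", "lycopodiophyte", "pteridophyte")
VERTEBRATE_SUBGROUPS = ("bird", "mammal", "amphibian", "reptile")

SUBGROUP_LINEAGE = {**{s: "tracheophyte" for s in PLANT_SUBGROUPS},
                    **{s: "vertebrate" for s in VERTEBRATE_SUBGROUPS}}

#: Species metadata columns, in canonical CSV order.
METADATA_COLUMNS = ["species_id", "scientific_name", "lineage", "subgroup",
                    "class", "order", "family", "iucn_status",
                    "n_occurrences", "alien"]


class RelationshipValue(enum.Enum):
    """Signed relationship of one species with one NCP."""

    POSITIVE = 1
    NEUTRAL = 0
    NEGATIVE = -1
    NA_NO_INFO = "na_no_info"
    NA_NOT_APPLICABLE = "na_not_applicable"

    @property
    def is_na(self) -> bool:
        return self in (RelationshipValue.NA_NO_INFO,
                        RelationshipValue.NA_NOT_APPLICABLE)


@dataclass(frozen=True)
class SpeciesRecord:
    """Metadata for one species row."""

    species_id: str
    scientific_name: str = ""
    lineage: str = "tracheophyte"
    subgroup: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    iucn_status: str = ""
    n_occurrences: int = 0
    alien: bool = False
    vernacular_names: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class Violation:
    """One validation-report entry."""

    rule: str
    species_id: str
    ncp_id: str
    message: str


class ValidationReport:
    """Collection of :class:`Violation` entries; empty means valid."""

    def __init__(self, violations: Sequence[Violation] = ()):
        self.violations = list(violations)

    @property
    def empty(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)

    def __iter__(self):
        return iter(self.violations)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(v.rule, v.species_id, v.ncp_id, v.message) for v in self.violations],
            columns=["rule", "species_id", "ncp_id", "message"])


@dataclass(frozen=True)
class ScoreSummary:
    """Per-species category and grand totals (signed sums over non-NA cells).

    ``negatives`` values are signed sums of the -1 cells (hence <= 0), so for
    every category ``totals[c] == positives[c] + negatives[c]``.
    """

    species_id: str
    totals: Mapping[str, int]
    positives: Mapping[str, int]
    negatives: Mapping[str, int]
    n_na: Mapping[str, int]
    grand_total: int
    grand_positive: int
    grand_negative: int


@dataclass(frozen=True)
class NCPSummary:
    """Per-NCP counts for one species group (lineage or subgroup)."""

    ncp_id: str
    group: str
    n_positive: int
    n_negative: int
    n_neutral: int
    n_na: int
    n_applicable: int  # species in the group for which the NCP applies


def percent(count: int, total: int) -> float:
    """Report ``100 * count / total`` rounded half-up to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    q = (Decimal(count) * 100 / Decimal(total)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(q)


class RelationshipTable:
    """Catalog + species metadata + a dense signed cell matrix.

    Parameters
    ----------
    catalog
        The :class:`~ncplink.catalog.NCPCatalog` the columns refer to.
    species
        DataFrame with at least ``species_id`` and ``lineage``; other
        metadata columns are filled with defaults when absent.
    cells
        DataFrame indexed by species_id with one float column per ncp_id;
        values in {1.0, 0.0, -1.0, NaN}.  NaN inside the applicable mask is
        ``NA_NO_INFO``; cells outside it are ``NA_NOT_APPLICABLE`` regardless
        of stored content (validation flags any stored value there).
    """

    def __init__(self, catalog: NCPCatalog, species: pd.DataFrame,
                 cells: pd.DataFrame):
        if species["species_id"].duplicated().any():
            dupes = species.loc[species["species_id"].duplicated(), "species_id"]
            raise TableValidationError(
                f"duplicate species_id(s): {sorted(set(dupes))}")
        self.catalog = catalog
        self.species = species.reset_index(drop=True).copy()
        for col, default in (("scientific_name", ""), ("subgroup", ""),
                             ("class", ""), ("order", ""), ("family", ""),
                             ("iucn_status", ""), ("n_occurrences", 0),
                             ("alien", False)):
            if col not in self.species.columns:
                self.species[col] = default
        unknown_cols = [c for c in cells.columns if c not in catalog]
        if unknown_cols:
            raise TableValidationError(f"unknown NCP column(s): {unknown_cols}")
        # align to full species x catalog grid, catalog column order
        self.cells = cells.reindex(index=self.species["species_id"],
                                   columns=catalog.ncp_ids).astype(float)

    # -- basic accessors ---------------------------------------------------

    @property
    def species_ids(self) -> list:
        return list(self.species["species_id"])

    @property
    def n_species(self) -> int:
        return len(self.species)

    def lineage_of(self, species_id: str) -> str:
        row = self.species.loc[self.species["species_id"] == species_id]
        if row.empty:
            raise UnknownSpeciesError([species_id])
        return row["lineage"].iloc[0]

    def applicable_matrix(self) -> pd.DataFrame:
        """Boolean species x NCP frame: True where the NCP applies."""
        masks = {lin: applicability_mask(self.catalog, lin) for lin in LINEAGES
                 if lin in set(self.species["lineage"])}
        rows = []
        for lin in self.species["lineage"]:
            mask = masks.get(lin, set())
            rows.append([c in mask for c in self.catalog.ncp_ids])
        return pd.DataFrame(rows, index=self.cells.index,
                            columns=self.catalog.ncp_ids)

    def value_at(self, species_id: str, ncp_id: str) -> RelationshipValue:
        if ncp_id not in self.catalog:
            raise UnknownNCPError(f"unknown ncp_id {ncp_id!r}")
        if species_id not in self.cells.index:
            raise UnknownSpeciesError([species_id])
        if not self.catalog.get(ncp_id).applies_to(self.lineage_of(species_id)):
            return RelationshipValue.NA_NOT_APPLICABLE
        raw = self.cells.at[species_id, ncp_id]
        if pd.isna(raw):
            return RelationshipValue.NA_NO_INFO
        return RelationshipValue(int(raw))

    def subset(self, species_ids: Iterable[str]) -> "RelationshipTable":
        keep = set(species_ids)
        missing = keep - set(self.species_ids)
        if missing:
            raise UnknownSpeciesError(missing)
        sp = self.species[self.species["species_id"].isin(keep)]
        return RelationshipTable(self.catalog, sp,
                                 self.cells.loc[sp["species_id"]])

    def filter_species(self, min_occurrences: int = 10,
                       exclude_alien: bool = True) -> "RelationshipTable":
        """Apply the occurrence-count and alien filters; order preserved."""
        sp = filter_species_frame(self.species, min_occurrences, exclude_alien)
        return RelationshipTable(self.catalog, sp, self.cells.loc[sp["species_id"]])


# -- validation -----------------------------------------------------------

def validate_table(table: RelationshipTable) -> ValidationReport:
    """Check every cell-level invariant; violations become report entries."""
    violations = []
    app = table.applicable_matrix()
    cells = table.cells
    for _, row in table.species.iterrows():
        sid, lin, sub = row["species_id"], row["lineage"], row["subgroup"]
        if lin not in LINEAGES:
            violations.append(Violation("unknown_lineage", sid, "",
                                        f"unknown lineage {lin!r}"))
            continue
        if sub and SUBGROUP_LINEAGE.get(sub) not in (None, lin):
            violations.append(Violation(
                "subgroup_lineage_mismatch", sid, "",
                f"subgroup {sub!r} inconsistent with lineage {lin!r}"))
    valid_values = {1.0, 0.0, -1.0}
    for ncp in table.catalog:
        col = cells[ncp.ncp_id]
        app_col = app[ncp.ncp_id]
        for sid, raw in col.items():
            if pd.isna(raw):
                continue
            if not app_col.loc[sid]:
                violations.append(Violation(
                    "value_at_inapplicable_cell", sid, ncp.ncp_id,
                    f"value {raw:g} stored where the NCP does not apply"))
                continue
            if raw not in valid_values:
                violations.append(Violation(
                    "value_out_of_domain", sid, ncp.ncp_id,
                    f"value {raw!r} outside {{1, 0, -1, NA}}"))
            elif raw == -1.0 and not ncp.negative_allowed:
                violations.append(Violation(
                    "negative_not_allowed", sid, ncp.ncp_id,
                    "negative value where the NCP does not admit one"))
    return ValidationReport(violations)


# -- I/O ------------------------------------------------------------------

_ACCEPTED = {"1": 1.0, "+1": 1.0, "0": 0.0, "-1": -1.0, "−1": -1.0,
             "": np.nan, "NA": np.nan, "na": np.nan, "NaN": np.nan}


def read_relationship_table(path, catalog: NCPCatalog,
                            validate: bool = True) -> RelationshipTable:
    """Read a relationship-table CSV against ``catalog``.

    Empty strings in NCP columns become ``NA_NO_INFO`` where the NCP applies
    (and are simply not stored where it does not).  With ``validate=True``
    (default) a non-empty validation report raises
    :class:`~ncplink.errors.TableValidationError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("species_id", "lineage") if c not in df.columns]
    if missing:
        raise TableValidationError(f"{path}: missing metadata column(s) {missing}")
    meta_cols = [c for c in df.columns
                 if c in METADATA_COLUMNS or c.startswith("vernacular_")]
    ncp_cols = [c for c in df.columns if c not in meta_cols]
    unknown = [c for c in ncp_cols if c not in catalog]
    if unknown:
        raise TableValidationError(f"{path}: unknown NCP column(s) {unknown}")

    species = df[meta_cols].copy()
    if "n_occurrences" in species.columns:
        species["n_occurrences"] = pd.to_numeric(
            species["n_occurrences"], errors="coerce").fillna(0).astype(int)
    if "alien" in species.columns:
        species["alien"] = species["alien"].str.strip().str.lower().isin(
            ("true", "1", "yes"))

    values = {}
    for col in ncp_cols:
        parsed = []
        for sid, raw in zip(df["species_id"], df[col]):
            token = raw.strip()
            if token not in _ACCEPTED:
                raise CellValueError(sid, col, raw)
            parsed.append(_ACCEPTED[token])
        values[col] = parsed
    cells = pd.DataFrame(values, index=df["species_id"])
    table = RelationshipTable(catalog, species, cells)
    if validate:
        report = validate_table(table)
        if not report.empty:
            first = report.violations[0]
            raise TableValidationError(
                f"{path}: {len(report)} validation violation(s); first: "
                f"[{first.rule}] {first.species_id}/{first.ncp_id} {first.message}",
                report=report)
    return table


def write_relationship_table(table: RelationshipTable, path) -> None:
    """Write CSV with +1 as "1", -1 as "-1", 0 as "0" and NA as empty."""
    meta = table.species.copy()
    extra = [c for c in meta.columns if c.startswith("vernacular_")]
    meta = meta[[c for c in METADATA_COLUMNS if c in meta.columns] + extra]
    meta["alien"] = np.where(meta["alien"], "true", "false")
    app = table.applicable_matrix()
    out = meta.copy()
    for ncp_id in table.catalog.ncp_ids:
        col = table.cells[ncp_id].to_numpy()
        text = np.where(np.isnan(col), "",
                        np.char.mod("%d", np.nan_to_num(col).astype(int)))
        # inapplicable cells are written empty too (single NA on disk)
        text = np.where(app[ncp_id].to_numpy(), text, "")
        out[ncp_id] = text
    out.to_csv(path, index=False)


# -- aggregation ----------------------------------------------------------

def species_score_summary(table: RelationshipTable,
                          species_id: str) -> ScoreSummary:
    """Table-1-style totals for one species.

    Sums run over the species' applicable NCPs only; NA cells contribute 0
    and are counted in ``n_na`` per category.
    """
    if species_id not in table.cells.index:
        raise UnknownSpeciesError([species_id])
    lineage = table.lineage_of(species_id)
    mask = applicability_mask(table.catalog, lineage)
    row = table.cells.loc[species_id]
    totals, positives, negatives, n_na = {}, {}, {}, {}
    for cat in CATEGORIES:
        ids = [n for n in table.catalog.category_ids(cat) if n in mask]
        vals = row[ids]
        positives[cat] = int((vals == 1).sum())
        negatives[cat] = -int((vals == -1).sum())
        totals[cat] = positives[cat] + negatives[cat]
        n_na[cat] = int(vals.isna().sum())
    return ScoreSummary(
        species_id=species_id,
        totals=totals, positives=positives, negatives=negatives, n_na=n_na,
        grand_total=sum(totals.values()),
        grand_positive=sum(positives.values()),
        grand_negative=sum(negatives.values()),
    )


def _group_column(table: RelationshipTable, group_by: str) -> pd.Series:
    if group_by not in ("lineage", "subgroup"):
        raise ValueError(f"group_by must be 'lineage' or 'subgroup', got {group_by!r}")
    return table.species.set_index("species_id")[group_by]


def _group_lineage(group_by: str, group: str) -> str:
    return group if group_by == "lineage" else SUBGROUP_LINEAGE.get(group, "")


def ncp_summary(table: RelationshipTable, ncp_id: str,
                group_by: str = "lineage") -> list:
    """Per-group sign counts for one NCP.

    Counts partition the applicable species of each group:
    ``n_positive + n_negative + n_neutral + n_na == n_applicable``.
    Groups whose lineage the NCP does not apply to get all-zero counts.
    """
    ncp = table.catalog.get(ncp_id)
    groups = _group_column(table, group_by)
    col = table.cells[ncp_id]
    out = []
    for group in sorted(set(groups)):
        members = groups[groups == group].index
        if not ncp.applies_to(_group_lineage(group_by, group)):
            out.append(NCPSummary(ncp_id, group, 0, 0, 0, 0, 0))
            continue
        vals = col.loc[members]
        out.append(NCPSummary(
            ncp_id=ncp_id, group=group,
            n_positive=int((vals == 1).sum()),
            n_negative=int((vals == -1).sum()),
            n_neutral=int((vals == 0).sum()),
            n_na=int(vals.isna().sum()),
            n_applicable=len(members)))
    return out


def summarize_all(table: RelationshipTable,
                  group_by: str = "lineage") -> pd.DataFrame:
    """One row per (group, NCP) with counts and percentages.

    Rows exist only where the NCP applies to the group's lineage, so the
    built-in catalog yields ``16 x |plant groups| + 9 x |vertebrate groups|``
    rows.  Percentages use the half-up single-decimal rule of :func:`percent`.
    """
    frames = []
    for ncp_id in table.catalog.ncp_ids:
        for s in ncp_summary(table, ncp_id, group_by):
            if s.n_applicable == 0 and not table.catalog.get(ncp_id).applies_to(
                    _group_lineage(group_by, s.group)):
                continue
            frames.append({
                "group": s.group, "ncp_id": ncp_id,
                "category": table.catalog.category_of(ncp_id),
                "n_positive": s.n_positive, "n_negative": s.n_negative,
                "n_neutral": s.n_neutral, "n_na": s.n_na,
                "n_applicable": s.n_applicable,
                "pct_positive": percent(s.n_positive, s.n_applicable)
                if s.n_applicable else float("nan"),
                "pct_negative": percent(s.n_negative, s.n_applicable)
                if s.n_applicable else float("nan"),
            })
    return pd.DataFrame(frames).sort_values(
        ["group", "ncp_id"], kind="stable").reset_index(drop=True)


def count_relationships(table: RelationshipTable) -> tuple:
    """Return ``(n_reported, n_possible)``.

    ``n_possible`` is the number of applicable (species, NCP) pairs;
    ``n_reported`` excludes the ``NA_NO_INFO`` cells.
    """
    app = table.applicable_matrix().to_numpy()
    n_possible = int(app.sum())
    na = np.isnan(table.cells.to_numpy()) & app
    return n_possible - int(na.sum()), n_possible


def filter_species_frame(species: pd.DataFrame, min_occurrences: int = 10,
                         exclude_alien: bool = True) -> pd.DataFrame:
    if min_occurrences < 0:
        raise ValueError("min_occurrences must be >= 0")
    keep = species["n_occurrences"] >= min_occurrences
    if exclude_alien:
        keep &= ~species["alien"].astype(bool)
    return species[keep].reset_index(drop=True)


def filter_species(records: Sequence[SpeciesRecord], min_occurrences: int = 10,
                   exclude_alien: bool = True) -> list:
    """Retain records with enough occurrences, optionally dropping aliens."""
    if min_occurrences < 0:
        raise ValueError("min_occurrences must be >= 0")
    return [r for r in records
            if r.n_occurrences >= min_occurrences
            and not (exclude_alien and r.alien)]


def apply_synonym_map(table: RelationshipTable, mapping: Mapping[str, str],
                      policy: str = "information_preserving") -> RelationshipTable:
    """Merge synonym rows into their canonical species.

    ``mapping`` sends old ids to canonical ids; unmapped ids are canonical
    already.  Cells merge element-wise: non-NA beats NA, equal non-NA values
    are kept, and differing non-NA values raise
    :class:`~ncplink.errors.MergeConflictError` under both the default
    ``information_preserving`` and the ``strict`` policy (under ``strict``
    even an NA/non-NA mix with >1 distinct non-NA is a conflict — identical
    to the default in practice since equal values never conflict).
    Occurrence counts are summed over merged rows; other metadata comes from
    the first row encountered.
    """
    if policy not in ("information_preserving", "strict"):
        raise ValueError(f"unknown merge policy {policy!r}")
    canon = {sid: mapping.get(sid, sid) for sid in table.species_ids}
    order = []
    members: dict = {}
    for sid in table.species_ids:
        c = canon[sid]
        if c not in members:
            members[c] = []
            order.append(c)
        members[c].append(sid)

    sp_rows, cell_rows = [], []
    sp_indexed = table.species.set_index("species_id", drop=False)
    for c in order:
        group = members[c]
        first = sp_indexed.loc[group[0]].copy()
        first["species_id"] = c
        first["n_occurrences"] = int(sp_indexed.loc[group, "n_occurrences"].sum())
        sp_rows.append(first)
        block = table.cells.loc[group]
        merged = []
        for ncp_id in table.catalog.ncp_ids:
            vals = block[ncp_id].dropna().unique()
            if len(vals) > 1:
                raise MergeConflictError(
                    f"conflicting values {sorted(vals)} for cell "
                    f"({c!r}, {ncp_id!r}) while merging {group}")
            merged.append(vals[0] if len(vals) else np.nan)
        cell_rows.append(merged)

    species = pd.DataFrame(sp_rows).reset_index(drop=True)
    cells = pd.DataFrame(cell_rows, index=[r["species_id"] for r in sp_rows],
                         columns=table.catalog.ncp_ids)
    return RelationshipTable(table.catalog, species, cells)


def top_scored_species(table: RelationshipTable, lineage: str = None,
                       n: int = 5) -> list:
    """Rank species by positive-relationship count, Table-1 style.

    Sorted by ``grand_positive`` descending, ties by ``grand_total``
    descending, then ``species_id`` ascending.  Returns at most ``n``
    summaries (all of them when ``n`` exceeds the species count).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ids = table.species_ids
    if lineage is not None:
        if lineage not in LINEAGES:
            raise ValueError(f"unknown lineage {lineage!r}")
        ids = [s for s, l in zip(table.species_ids, table.species["lineage"])
               if l == lineage]
    summaries = [species_score_summary(table, s) for s in ids]
    summaries.sort(key=lambda s: (-s.grand_positive, -s.grand_total, s.species_id))
    return summaries[:n]


def score_frame(table: RelationshipTable, species_ids=None) -> pd.DataFrame:
    """Vectorised ScoreSummary as a DataFrame (one row per species)."""
    if species_ids is None:
        species_ids = table.species_ids
    app = table.applicable_matrix()
    cells = table.cells.where(app)
    out = pd.DataFrame(index=pd.Index(species_ids, name="species_id"))
    for cat in CATEGORIES:
        ids = table.catalog.category_ids(cat)
        block = cells.loc[species_ids, ids]
        out[f"positive_{cat}"] = (block == 1).sum(axis=1).astype(int)
        out[f"negative_{cat}"] = -(block == -1).sum(axis=1).astype(int)
        out[f"total_{cat}"] = out[f"positive_{cat}"] + out[f"negative_{cat}"]
        out[f"n_na_{cat}"] = (block.isna() &
                              app.loc[species_ids, ids]).sum(axis=1).astype(int)
    out["grand_positive"] = sum(out[f"positive_{c}"] for c in CATEGORIES)
    out["grand_negative"] = sum(out[f"negative_{c}"] for c in CATEGORIES)
    out["grand_total"] = out["grand_positive"] + out["grand_negative"]
    return out
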