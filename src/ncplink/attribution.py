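"""Attribution rules turning raw evidence into relationship-cell values.

Three evidence routes are supported, mirroring how such tables are compiled
in practice:

* membership lists (e.g. crop-wild-relative or Emerald lists) mapped to a
  fixed value for members and neutral for everyone else;
* reference-count thresholding: species whose publication / weblink count
  exceeds the third quartile of their group's distribution get ``+1``;
* free-form evidence records merged per cell under an explicit policy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .catalog import NCPCatalog
from .errors import NcplinkError, UnknownNCPError
from .table import RelationshipValue

#: Source precedence (highest first) for the ``source_precedence`` policy.
SOURCE_RANK = {"expert": 0, "reference": 1, "analytics": 2}

MERGE_POLICIES = ("negative_dominance", "source_precedence")

QUANTILE_METHODS = ("linear", "lower", "higher", "nearest", "midpoint")


@dataclass(frozen=True)
class EvidenceRecord:
    """One piece of evidence proposing a value for a (species, NCP) cell."""

    species_id: str
    ncp_id: str
    source: str  # reference | expert | analytics
    proposed_value: int  # +1, 0 or -1
    note: str = ""

    def __post_init__(self):
        if self.source not in SOURCE_RANK:
            raise ValueError(f"unknown evidence source {self.source!r}")
        if self.proposed_value not in (1, 0, -1):
            raise ValueError(
                f"proposed_value must be one of 1, 0, -1; got {self.proposed_value!r}")


def assign_membership(species: Iterable[str], member_list: Iterable[str],
                      value_if_member: int = 1) -> dict:
    """Members of the list get ``value_if_member``; everyone else gets 0.

    Members absent from ``species`` are ignored with a warning; the result
    has exactly one assignment per species.
    """
    if value_if_member not in (1, -1):
        raise ValueError("value_if_member must be +1 or -1")
    species = list(species)
    members = set(member_list)
    unknown = members - set(species)
    if unknown:
        warnings.warn(
            f"{len(unknown)} member id(s) not in the species set ignored: "
            f"{sorted(unknown)[:5]}{'...' if len(unknown) > 5 else ''}",
            stacklevel=2)
    return {s: (value_if_member if s in members else 0) for s in species}


def third_quartile(values, method: str = "linear") -> float:
    """Q3 of ``values`` under a named quantile convention.

    ``linear`` interpolates between order statistics at index
    ``h = 0.75 * (n - 1)`` — the default of mainstream numerical
    environments.
    """
    if method not in QUANTILE_METHODS:
        raise ValueError(f"unknown quantile method {method!r}")
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take a quartile of an empty collection")
    return float(np.quantile(arr, 0.75, method=method))


def quartile_threshold(counts: Mapping[str, int], method: str = "linear",
                       groups: Optional[Mapping[str, str]] = None) -> dict:
    """Flag species whose count is strictly greater than their group's Q3.

    Parameters
    ----------
    counts
        species_id -> non-negative reference count.
    method
        Quantile convention passed to :func:`third_quartile`.
    groups
        Optional species_id -> group key (e.g. lineage); the quartile is
        then computed within each group separately.  Without it all species
        form one group.

    Returns
    -------
    dict
        species_id -> +1 for counts strictly above Q3, else 0.
    """
    counts = dict(counts)
    if not counts:
        raise ValueError("counts table is empty")
    for sid, c in counts.items():
        if c < 0:
            raise ValueError(f"negative count for species {sid!r}")
    if groups is None:
        group_of = {sid: "_all" for sid in counts}
    else:
        group_of = {sid: groups[sid] for sid in counts}
    out = {}
    for group in set(group_of.values()):
        members = [sid for sid in counts if group_of[sid] == group]
        q3 = third_quartile([counts[sid] for sid in members], method=method)
        for sid in members:
            out[sid] = 1 if counts[sid] > q3 else 0
    return {sid: out[sid] for sid in counts}  # original key order


def read_reference_counts(path) -> dict:
    """Read a ``species_id,count`` CSV into an ordered dict."""
    df = pd.read_csv(path, dtype={"species_id": str, "count": int})
    missing = [c for c in ("species_id", "count") if c not in df.columns]
    if missing:
        raise NcplinkError(f"{path}: missing column(s) {missing}")
    return dict(zip(df["species_id"], df["count"].astype(int)))


def _resolve(values: list) -> RelationshipValue:
    """Negative dominance: -1 beats +1 beats 0."""
    if -1 in values:
        return RelationshipValue.NEGATIVE
    if 1 in values:
        return RelationshipValue.POSITIVE
    return RelationshipValue.NEUTRAL


def merge_evidence(records: Iterable[EvidenceRecord],
                   policy: str = "negative_dominance",
                   catalog: Optional[NCPCatalog] = None,
                   cells: Optional[Iterable[tuple]] = None) -> dict:
    """Combine evidence records into one value per (species, NCP) cell.

    Policies
    --------
    ``negative_dominance`` (default)
        -1 beats +1 beats 0, over all records of the cell.
    ``source_precedence``
        Only records from the best-ranked source present (expert >
        reference > analytics) count; negative dominance breaks ties
        within that source.

    Cells named in ``cells`` but backed by no record become
    ``NA_NO_INFO``.  The result is independent of record order.
    """
    if policy not in MERGE_POLICIES:
        raise ValueError(f"unknown merge policy {policy!r}")
    by_cell: dict = {}
    for rec in records:
        if catalog is not None:
            if rec.ncp_id not in catalog:
                raise UnknownNCPError(f"unknown ncp_id {rec.ncp_id!r} in evidence")
            if rec.proposed_value == -1 and not catalog.get(rec.ncp_id).negative_allowed:
                raise NcplinkError(
                    f"evidence proposes -1 for {rec.ncp_id!r}, which does not "
                    f"admit negative values (species {rec.species_id!r})")
        by_cell.setdefault((rec.species_id, rec.ncp_id), []).append(rec)

    out = {}
    for cell, recs in by_cell.items():
        if policy == "source_precedence":
            best = min(SOURCE_RANK[r.source] for r in recs)
            recs = [r for r in recs if SOURCE_RANK[r.source] == best]
        out[cell] = _resolve([r.proposed_value for r in recs])
    if cells is not None:
        for cell in cells:
            out.setdefault(tuple(cell), RelationshipValue.NA_NO_INFO)
    return out


def read_evidence(path) -> list:
    """Read an evidence CSV (species_id,ncp_id,source,proposed_value[,note])."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["species_id", "ncp_id", "source", "proposed_value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise NcplinkError(f"{path}: missing column(s) {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(EvidenceRecord(
            species_id=row["species_id"], ncp_id=row["ncp_id"],
            source=row["source"],
            proposed_value=int(row["proposed_value"]),
            note=row.get("note", "")))
    return records
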