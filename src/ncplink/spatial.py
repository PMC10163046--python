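"""Per-pixel NCP index on occurrence grids.

The index for a pixel and an NCP category is::

    index = (sum of per-species category scores) / (number of species observed)
            * pixel area [km^2]

Pixels with no observed species have an undefined index (no-data), which is
distinct from an index of exactly zero (all observed species neutral).
Coordinates are assumed planar in km-compatible units; a cell of side
``cell_size`` has nominal area ``cell_size ** 2`` km^2, optionally clipped by
a boundary polygon (border pixels get their clipped area).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from shapely import wkt as shapely_wkt
from shapely.geometry import box

from .catalog import CATEGORIES
from .errors import NcplinkError, UnknownSpeciesError
from .table import RelationshipTable, score_frame

NODATA = -9999.0

DENOMINATORS = ("observed", "informative")


@dataclass(frozen=True)
class GridSpec:
    """Regular grid: lower-left origin, square cells, rows counted from top.

    Cells are half-open: a point on a cell's lower/left edge belongs to that
    cell; ``pixel_id`` is ``r{row}c{col}`` with row 0 the northernmost.
    """

    x0: float
    y0: float
    cell_size: float
    ncols: int
    nrows: int
    boundary_wkt: Optional[str] = None

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError("grid must have at least one row and one column")

    def locate(self, x: float, y: float):
        """(row, col) of the containing cell, or None if outside the extent."""
        col = math.floor((x - self.x0) / self.cell_size)
        row_from_bottom = math.floor((y - self.y0) / self.cell_size)
        if not (0 <= col < self.ncols and 0 <= row_from_bottom < self.nrows):
            return None
        return self.nrows - 1 - row_from_bottom, col

    def cell_box(self, row: int, col: int):
        x_lo = self.x0 + col * self.cell_size
        y_lo = self.y0 + (self.nrows - 1 - row) * self.cell_size
        return box(x_lo, y_lo, x_lo + self.cell_size, y_lo + self.cell_size)


def pixel_id(row: int, col: int) -> str:
    return f"r{row}c{col}"


@dataclass
class OccurrenceGrid:
    """Pixels with clipped area and the set of species observed in each.

    ``pixels`` columns: pixel_id, row, col, area_km2, species_present
    (frozenset).  Pixels fully outside the boundary polygon are dropped.
    """

    pixels: pd.DataFrame
    spec: GridSpec

    def __post_init__(self):
        if self.pixels["pixel_id"].duplicated().any():
            raise NcplinkError("duplicate pixel_ids in occurrence grid")
        if (self.pixels["area_km2"] <= 0).any():
            raise NcplinkError("pixel areas must be positive")

    @property
    def species_observed(self) -> set:
        out: set = set()
        for s in self.pixels["species_present"]:
            out |= s
        return out


def rasterize_occurrences(records: pd.DataFrame, spec: GridSpec,
                          species_filter: Optional[Iterable[str]] = None):
    """Bin point occurrence records onto the grid.

    Parameters
    ----------
    records
        DataFrame with columns ``species_id``, ``x``, ``y`` (and optionally
        ``year``, ignored here — temporal filtering happens upstream).
    spec
        Grid geometry; points outside the extent are dropped and counted.
    species_filter
        If given, only these species are kept (others counted as filtered).

    Returns
    -------
    (OccurrenceGrid, dict)
        The grid plus a report: ``n_records``, ``n_dropped_outside``,
        ``n_dropped_filtered``.
    """
    required = [c for c in ("species_id", "x", "y") if c not in records.columns]
    if required:
        raise NcplinkError(f"occurrence records missing column(s) {required}")
    keep_species = set(species_filter) if species_filter is not None else None

    present: dict = {(r, c): set()
                     for r in range(spec.nrows) for c in range(spec.ncols)}
    n_outside = n_filtered = 0
    for sid, x, y in zip(records["species_id"], records["x"], records["y"]):
        if keep_species is not None and sid not in keep_species:
            n_filtered += 1
            continue
        loc = spec.locate(float(x), float(y))
        if loc is None:
            n_outside += 1
            continue
        present[loc].add(sid)

    boundary = shapely_wkt.loads(spec.boundary_wkt) if spec.boundary_wkt else None
    nominal = spec.cell_size ** 2
    rows = []
    for r in range(spec.nrows):
        for c in range(spec.ncols):
            if boundary is not None:
                area = spec.cell_box(r, c).intersection(boundary).area
                if area <= 0:
                    continue
            else:
                area = nominal
            rows.append((pixel_id(r, c), r, c, area, frozenset(present[(r, c)])))
    pixels = pd.DataFrame(
        rows, columns=["pixel_id", "row", "col", "area_km2", "species_present"])
    report = {"n_records": len(records), "n_dropped_outside": n_outside,
              "n_dropped_filtered": n_filtered}
    return OccurrenceGrid(pixels, spec), report


@dataclass
class NCPIndexGrid:
    """Per-pixel index values for one category.

    ``data`` columns: pixel_id, row, col, area_km2, n_species, index
    (NaN where undefined, i.e. no species observed).
    """

    data: pd.DataFrame
    category: str
    metadata: Mapping = field(default_factory=dict)


def compute_ncp_index(grid: OccurrenceGrid, table: RelationshipTable,
                      category: str,
                      denominator: str = "observed") -> NCPIndexGrid:
    """Mean per-species category score, scaled by pixel area.

    ``denominator`` selects who counts as "species observed": ``observed``
    (default — every species present in the pixel, even if all its category
    cells are NA) or ``informative`` (only species with at least one non-NA
    cell in the category).
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
    if denominator not in DENOMINATORS:
        raise ValueError(f"unknown denominator rule {denominator!r}")
    observed = grid.species_observed
    missing = observed - set(table.species_ids)
    if missing:
        raise UnknownSpeciesError(missing)

    scores = score_frame(table)
    total = scores[f"total_{category}"]
    informative = scores[f"n_na_{category}"] < _applicable_in_category(table, category)

    rows = []
    for _, px in grid.pixels.iterrows():
        species = px["species_present"]
        if denominator == "informative":
            species = {s for s in species if informative.loc[s]}
        n = len(species)
        if n == 0:
            idx = np.nan
        else:
            idx = sum(total.loc[s] for s in species) / n * px["area_km2"]
        rows.append((px["pixel_id"], px["row"], px["col"], px["area_km2"],
                     n, idx))
    data = pd.DataFrame(rows, columns=["pixel_id", "row", "col", "area_km2",
                                       "n_species", "index"])
    meta = {"category": category, "denominator": denominator,
            "n_species_in_table": table.n_species}
    return NCPIndexGrid(data, category, meta)


def _applicable_in_category(table: RelationshipTable, category: str) -> pd.Series:
    """Per-species count of applicable NCPs within ``category``."""
    app = table.applicable_matrix()
    ids = table.catalog.category_ids(category)
    return app[ids].sum(axis=1)


def compute_all_indices(grid: OccurrenceGrid, table: RelationshipTable,
                        denominator: str = "observed") -> dict:
    """One :class:`NCPIndexGrid` per category."""
    return {c: compute_ncp_index(grid, table, c, denominator) for c in CATEGORIES}


def index_table(grids: Mapping[str, NCPIndexGrid]) -> pd.DataFrame:
    """Combine per-category grids into one frame with index_<category> columns."""
    base = None
    for cat in CATEGORIES:
        g = grids[cat].data.rename(columns={"index": f"index_{cat}"})
        base = g if base is None else base.merge(
            g[["pixel_id", f"index_{cat}"]], on="pixel_id")
    return base


def write_index_grid(grid: NCPIndexGrid, fmt: str, path,
                     metadata: Optional[Mapping] = None) -> None:
    """Write one category grid as CSV or ESRI ASCII raster (``asc``).

    Undefined pixels become empty CSV cells / the raster NODATA value; a
    sidecar ``<path>.meta.json`` records category and settings.
    """
    meta = dict(grid.metadata)
    if metadata:
        meta.update(metadata)
    if fmt == "csv":
        out = grid.data.copy()
        out.to_csv(path, index=False, float_format="%.9f")
    elif fmt == "asc":
        _write_asc(grid, path, meta)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'asc'")
    with open(f"{path}.meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def _write_asc(grid: NCPIndexGrid, path, meta: Mapping = ()) -> None:
    meta = dict(meta)
    nrows = int(grid.data["row"].max()) + 1
    ncols = int(grid.data["col"].max()) + 1
    arr = np.full((nrows, ncols), NODATA)
    for _, px in grid.data.iterrows():
        v = px["index"]
        arr[int(px["row"]), int(px["col"])] = NODATA if pd.isna(v) else v
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n")
        fh.write(f"xllcorner {meta.get('x0', 0):g}\n"
                 f"yllcorner {meta.get('y0', 0):g}\n"
                 f"cellsize {meta.get('cell_size', 1):g}\n")
        fh.write(f"NODATA_value {NODATA:g}\n")
        for r in range(nrows):
            fh.write(" ".join(f"{v:.9g}" for v in arr[r]) + "\n")


def read_index_grid(path, category: str = "") -> NCPIndexGrid:
    """Read back a CSV written by :func:`write_index_grid`."""
    data = pd.read_csv(path)
    return NCPIndexGrid(data, category)
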